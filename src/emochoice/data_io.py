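"""Reading, validating, merging and writing long-format emotion/choice panels.

A *panel* is the tidy long table produced by a consumer study in which every
subject tastes every product once and scores overall liking (100-mm VAS,
0-100) plus a fixed battery of emotion items (each on the 0-4 intensity
scale).  One file row is one (subject, product) trial.  The choice column, when
present, flags the single product each subject later picked for actual
consumption (1 = chosen, 0 = not).

Files are plain delimited text (tab or comma, ``.`` decimals); anything more
exotic must be normalised upstream.  Column names are mapped through a
:class:`PanelSchema`, so arbitrary headers can be absorbed via a small YAML
config instead of code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelError",
    "SchemaError",
    "PanelValidationError",
    "PanelSchema",
    "EmotionPanel",
    "read_panel",
    "merge_choice",
    "write_report",
]

#: canonical internal column names
SUBJECT, PRODUCT, LIKING, CHOSEN = "subject", "product", "liking", "chosen"

LIKING_RANGE = (0.0, 100.0)
EMOTION_RANGE = (0.0, 4.0)


class PanelError(ValueError):
    """Base class for panel I/O and validation failures."""


class SchemaError(PanelError):
    """A required column is missing or the schema config is malformed."""


class PanelValidationError(PanelError):
    """The table parsed but violates a panel invariant."""


@dataclass
class PanelSchema:
    """Mapping from file column headers to the canonical panel fields.

    ``emotions=None`` means "every column not otherwise claimed, in file
    order" -- convenient because the emotion batteries have 12 or 39 items
    and listing them is error-prone.
    """

    subject: str = SUBJECT
    product: str = PRODUCT
    liking: str = LIKING
    choice: str | None = CHOSEN
    emotions: list[str] | None = None
    instrument: str = "emotions"
    alternatives: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSchema":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise SchemaError(f"schema file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class EmotionPanel:
    """Complete-block subject x product panel with liking, optional choice and
    an ordered emotion-score vector per trial.

    ``data`` holds canonical columns ``subject, product, liking[, chosen]``
    followed by the emotion columns in instrument order.  Row order is
    preserved from the source and defines the row order of every derived
    matrix downstream.
    """

    data: pd.DataFrame
    instrument: str
    emotion_names: list[str]
    alternatives: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.alternatives:
            self.alternatives = sorted(self.data[PRODUCT].astype(str).unique())
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def subjects(self) -> list:
        """Subject ids in order of first appearance."""
        return list(dict.fromkeys(self.data[SUBJECT]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def has_choice(self) -> bool:
        return CHOSEN in self.data.columns

    def emotion_matrix(self) -> np.ndarray:
        """(n_trials, n_emotions) float array in panel row order."""
        return self.data[self.emotion_names].to_numpy(dtype=float)

    def subject_rows(self, subject) -> pd.DataFrame:
        return self.data[self.data[SUBJECT] == subject]

    def drop_subject(self, subject) -> "EmotionPanel":
        kept = self.data[self.data[SUBJECT] != subject].reset_index(drop=True)
        return EmotionPanel(kept, self.instrument, list(self.emotion_names),
                            list(self.alternatives))

    def copy(self) -> "EmotionPanel":
        return EmotionPanel(self.data.copy(), self.instrument,
                            list(self.emotion_names), list(self.alternatives))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in (SUBJECT, PRODUCT, LIKING):
            if col not in df.columns:
                raise SchemaError(f"panel is missing mandatory column {col!r}")
        missing = [c for c in self.emotion_names if c not in df.columns]
        if missing:
            raise SchemaError(f"panel is missing emotion columns {missing}")
        numeric_cols = [LIKING, *self.emotion_names] + ([CHOSEN] if self.has_choice else [])
        na = df[numeric_cols].isna()
        if na.to_numpy().any():
            rows = sorted(df.index[na.any(axis=1)].tolist())
            raise PanelValidationError(
                f"missing/non-numeric values in rows {rows[:10]}"
                + (" ..." if len(rows) > 10 else ""))
        _check_range(df, LIKING, LIKING_RANGE)
        for col in self.emotion_names:
            _check_range(df, col, EMOTION_RANGE)
        # complete block: each subject has exactly one row per alternative
        alt = set(self.alternatives)
        counts = df.groupby(SUBJECT, sort=False)[PRODUCT].agg(list)
        for subj, prods in counts.items():
            prods = [str(p) for p in prods]
            if len(prods) != len(alt) or set(prods) != alt or len(set(prods)) != len(prods):
                raise PanelValidationError(
                    f"subject {subj!r} does not have exactly one row per "
                    f"alternative {sorted(alt)}; got {sorted(prods)}")
        if self.has_choice:
            if not df[CHOSEN].isin([0, 1]).all():
                bad = sorted(df.index[~df[CHOSEN].isin([0, 1])].tolist())
                raise PanelValidationError(f"choice flag not in {{0,1}} at rows {bad[:10]}")
            per_subj = df.groupby(SUBJECT, sort=False)[CHOSEN].sum()
            bad = per_subj[per_subj != 1]
            if len(bad):
                raise PanelValidationError(
                    "each subject must have exactly one chosen product; "
                    f"violated by subjects {list(bad.index)[:10]}")

    def chosen_products(self) -> pd.Series:
        """Chosen product id per subject (requires choice flags)."""
        if not self.has_choice:
            raise PanelValidationError("panel carries no choice flags")
        sel = self.data[self.data[CHOSEN] == 1]
        return sel.set_index(SUBJECT)[PRODUCT]

    def choice_shares(self) -> pd.Series:
        """Percent of subjects choosing each alternative (Table-4 style)."""
        chosen = self.chosen_products().astype(str)
        counts = chosen.value_counts().reindex(self.alternatives, fill_value=0)
        return 100.0 * counts / counts.sum()


def _check_range(df: pd.DataFrame, col: str, lim: tuple[float, float]) -> None:
    vals = df[col].to_numpy(dtype=float)
    bad = (vals < lim[0]) | (vals > lim[1])
    if bad.any():
        rows = sorted(np.flatnonzero(bad).tolist())
        raise PanelValidationError(
            f"column {col!r} outside [{lim[0]}, {lim[1]}] at rows {rows[:10]}"
            + (" ..." if len(rows) > 10 else ""))


def _sniff_sep(path: Path) -> str:
    first = path.open().readline()
    return "\t" if "\t" in first else ","


def read_panel(path: str | Path, schema: PanelSchema | None = None) -> EmotionPanel:
    """Read and validate a long-format panel file.

    Delimiter autodetection is limited to tab and comma with ``.`` decimals;
    anything else needs pre-conversion.  Emotion column order is preserved
    exactly as given in the file (or in ``schema.emotions``).
    """
    schema = schema or PanelSchema()
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]

    for role, name in ((SUBJECT, schema.subject), (PRODUCT, schema.product),
                       (LIKING, schema.liking)):
        if name not in df.columns:
            raise SchemaError(f"required column {name!r} (role {role}) not in {path.name}; "
                              f"available: {list(df.columns)}")
    rename = {schema.subject: SUBJECT, schema.product: PRODUCT, schema.liking: LIKING}
    has_choice = schema.choice is not None and schema.choice in df.columns
    if has_choice:
        rename[schema.choice] = CHOSEN
    df = df.rename(columns=rename)

    claimed = {SUBJECT, PRODUCT, LIKING} | ({CHOSEN} if has_choice else set())
    if schema.emotions is not None:
        missing = [c for c in schema.emotions if c not in df.columns]
        if missing:
            raise SchemaError(f"emotion columns {missing} not in {path.name}")
        emotion_names = list(schema.emotions)
    else:
        emotion_names = [c for c in df.columns if c not in claimed]
    if not emotion_names:
        raise SchemaError(f"no emotion columns found in {path.name}")

    numeric = [LIKING, *emotion_names] + ([CHOSEN] if has_choice else [])
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise PanelError(
                f"non-numeric value {df.loc[row, col]!r} in column {col!r}, row {row}")
        df[col] = parsed
    if has_choice:
        df[CHOSEN] = df[CHOSEN].astype(int)
    df[SUBJECT] = df[SUBJECT].astype(str)
    df[PRODUCT] = df[PRODUCT].astype(str)

    cols = [SUBJECT, PRODUCT, LIKING] + ([CHOSEN] if has_choice else []) + emotion_names
    alts = list(schema.alternatives) if schema.alternatives else []
    return EmotionPanel(df[cols].reset_index(drop=True), schema.instrument,
                        emotion_names, alternatives=alts)


def merge_choice(panel: EmotionPanel, choice_source: EmotionPanel) -> EmotionPanel:
    """Copy choice flags from ``choice_source`` onto ``panel`` by (subject, product).

    Used because one instrument's file carries the delayed-choice column while
    the other's does not.  Idempotent when the panel already holds identical
    flags.  Both panels must cover exactly the same (subject, product) keys.
    """
    if not choice_source.has_choice:
        raise PanelValidationError("choice source panel carries no choice flags")
    key = [SUBJECT, PRODUCT]
    left = set(map(tuple, panel.data[key].itertuples(index=False)))
    right = set(map(tuple, choice_source.data[key].itertuples(index=False)))
    if left != right:
        orphans = sorted(left ^ right)
        raise PanelError(f"(subject, product) key sets differ; orphan keys {orphans[:10]}")
    flags = choice_source.data.set_index(key)[CHOSEN]
    merged = panel.data.copy()
    merged[CHOSEN] = flags.loc[list(map(tuple, merged[key].itertuples(index=False)))].to_numpy()
    cols = [SUBJECT, PRODUCT, LIKING, CHOSEN, *panel.emotion_names]
    return EmotionPanel(merged[cols], panel.instrument, list(panel.emotion_names),
                        list(panel.alternatives))


# -- report writing ------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_report(results: Mapping[str, object], path: str | Path) -> list[Path]:
    """Write analysis results deterministically under directory ``path``.

    DataFrames become ``<name>.tsv`` with fixed numeric formatting and the
    row order they arrive in; plain mappings/sequences are pooled into
    ``summary.json`` with sorted keys.  Identical inputs yield byte-identical
    files.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict[str, object] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            target = outdir / f"{name}.tsv"
            obj.to_csv(target, sep="\t", index=False, float_format=_FLOAT_FMT,
                       lineterminator="\n")
            written.append(target)
        else:
            summary[name] = _jsonable(obj)
    if summary:
        target = outdir / "summary.json"
        target.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(target)
    return written


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def panels_equal(a: EmotionPanel, b: EmotionPanel, atol: float = 0.0) -> bool:
    """Exact (or atol-loose) equality of two panels, used for round-trip checks."""
    if a.emotion_names != b.emotion_names or a.alternatives != b.alternatives:
        return False
    if a.has_choice != b.has_choice:
        return False
    if list(a.data[SUBJECT]) != list(b.data[SUBJECT]):
        return False
    if list(a.data[PRODUCT]) != list(b.data[PRODUCT]):
        return False
    num_cols = [LIKING, *a.emotion_names] + ([CHOSEN] if a.has_choice else [])
    x = a.data[num_cols].to_numpy(dtype=float)
    y = b.data[num_cols].to_numpy(dtype=float)
    return bool(np.allclose(x, y, rtol=0.0, atol=atol))
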