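"""Core data model and text I/O for call corpora.

A :class:`Call` is one vocalization: identity labels (individual, call type,
vocal sequence), an f0 contour (time/Hz pairs, call-relative times), a
duration, a harmonics-to-noise ratio, and optionally a waveform. A
:class:`Corpus` is a list of calls plus provenance metadata.

On disk a corpus is a directory holding a delimited call table
(``calls.tsv``) and a ``contours/`` subdirectory with one two-column TSV (or
Praat PitchTier text) file per call. Waveforms are not persisted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Call",
    "Corpus",
    "Waveform",
    "SchemaError",
    "IntegrityError",
    "read_corpus",
    "write_corpus",
    "filter_corpus",
    "read_pitch_contour",
]

#: canonical call-table columns; aliases may be supplied at read time
REQUIRED_COLUMNS = ("call_id", "individual_id", "call_type", "sequence_id")
OPTIONAL_COLUMNS = ("duration", "hnr")


class SchemaError(ValueError):
    """A required column is missing or misnamed in an input table."""


class IntegrityError(ValueError):
    """The data violate a corpus invariant (e.g. duplicate call ids)."""


@dataclass
class Waveform:
    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Call:
    """One vocalization with its labels and acoustic descriptors."""

    call_id: str
    individual_id: str
    call_type: str
    sequence_id: str
    f0_contour: np.ndarray | None = None  # (n, 2) array of (time s, f0 Hz)
    duration: float = float("nan")
    hnr: float = float("nan")
    waveform: Waveform | None = None

    def __post_init__(self) -> None:
        if self.f0_contour is not None:
            c = np.asarray(self.f0_contour, dtype=float)
            if c.ndim != 2 or c.shape[1] != 2:
                raise ValueError(f"{self.call_id}: contour must be (n, 2)")
            if len(c) and np.any(np.diff(c[:, 0]) <= 0):
                raise ValueError(f"{self.call_id}: contour times must be strictly increasing")
            if len(c) and (c[0, 0] < -1e-9):
                raise ValueError(f"{self.call_id}: contour times must start at >= 0")
            if len(c) and np.any(c[:, 1] <= 0):
                raise ValueError(f"{self.call_id}: f0 values must be positive")
            self.f0_contour = c
            if np.isnan(self.duration):
                self.duration = float(c[-1, 0])
            elif len(c) and c[-1, 0] > self.duration + 1e-6:
                raise ValueError(f"{self.call_id}: contour exceeds stated duration")
        if not np.isnan(self.duration) and self.duration <= 0:
            raise ValueError(f"{self.call_id}: duration must be positive")
        if self.waveform is not None and not np.isnan(self.duration):
            if abs(self.waveform.duration - self.duration) > max(0.05, 0.1 * self.duration):
                raise ValueError(f"{self.call_id}: waveform length inconsistent with duration")


@dataclass
class Corpus:
    """An ordered collection of calls with provenance metadata."""

    calls: list[Call]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.call_id for c in self.calls]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate call_id(s): {dupes[:5]}")
        seq_owner: dict[str, str] = {}
        for c in self.calls:
            owner = seq_owner.setdefault(c.sequence_id, c.individual_id)
            if owner != c.individual_id:
                raise IntegrityError(
                    f"sequence {c.sequence_id!r} spans individuals {owner!r} and {c.individual_id!r}"
                )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __getitem__(self, call_id: str) -> Call:
        for c in self.calls:
            if c.call_id == call_id:
                return c
        raise KeyError(call_id)

    @property
    def call_ids(self) -> list[str]:
        return [c.call_id for c in self.calls]

    @property
    def individuals(self) -> list[str]:
        return sorted({c.individual_id for c in self.calls})

    @property
    def call_types(self) -> list[str]:
        return sorted({c.call_type for c in self.calls})

    @property
    def sequence_ids(self) -> list[str]:
        return sorted({c.sequence_id for c in self.calls})

    def to_frame(self) -> pd.DataFrame:
        """Label table, one row per call, indexed by call_id."""
        return pd.DataFrame(
            {
                "individual_id": [c.individual_id for c in self.calls],
                "call_type": [c.call_type for c in self.calls],
                "sequence_id": [c.sequence_id for c in self.calls],
                "duration": [c.duration for c in self.calls],
                "hnr": [c.hnr for c in self.calls],
            },
            index=pd.Index(self.call_ids, name="call_id"),
        )

    def subset(self, call_ids: Iterable[str], note: str | None = None) -> "Corpus":
        keep = set(call_ids)
        meta = dict(self.metadata)
        if note:
            meta["filters"] = list(meta.get("filters", [])) + [note]
        return Corpus([c for c in self.calls if c.call_id in keep], meta)

    def counts(self) -> pd.DataFrame:
        """Calls per individual (rows) and call type (columns)."""
        df = self.to_frame()
        return pd.crosstab(df["individual_id"], df["call_type"])


# ---------------------------------------------------------------------------
# contour file parsing


def read_pitch_contour(path: str | Path) -> np.ndarray:
    """Read an f0 contour from a two-column TSV or a Praat PitchTier text file.

    Returns an (n, 2) array of (time, Hz). Times are call-relative.
    """
    path = Path(path)
    text = path.read_text()
    if "PitchTier" in text.splitlines()[0] or "ooTextFile" in text:
        return _parse_pitchtier(text, path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: contour file needs two columns (time, Hz)")
    # tolerate a header row of column names
    if not np.issubdtype(np.asarray(df.iloc[0, :2]).dtype, np.number):
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
    return df.iloc[:, :2].astype(float).to_numpy()


def _parse_pitchtier(text: str, path: Path) -> np.ndarray:
    """Parse Praat PitchTier files (short or long text format)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    numbers: list[float] = []
    if any(ln.startswith("points [") or ln.startswith("number ") for ln in lines):
        # long format: 'number = t' / 'value = f' pairs
        for ln in lines:
            if ln.startswith(("number", "value")):
                numbers.append(float(ln.split("=")[1]))
    else:
        # short format: header (6 lines incl. xmin/xmax/n) then alternating t, f
        payload = []
        for ln in lines[2:]:
            try:
                payload.append(float(ln))
            except ValueError:
                continue
        if len(payload) < 3:
            raise SchemaError(f"{path}: unparseable PitchTier file")
        numbers = payload[3:]  # skip xmin, xmax, n points
    if len(numbers) % 2:
        raise SchemaError(f"{path}: odd number of PitchTier values")
    arr = np.asarray(numbers, dtype=float).reshape(-1, 2)
    arr[:, 0] -= arr[0, 0]  # make times call-relative
    return arr


# ---------------------------------------------------------------------------
# corpus I/O


def _resolve_columns(df: pd.DataFrame, aliases: Mapping[str, str] | None) -> pd.DataFrame:
    if aliases:
        df = df.rename(columns={v: k for k, v in aliases.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"call table is missing required column(s): {missing}")
    return df


def read_corpus(
    path: str | Path,
    format: str = "call_table",
    pitch_dir: str | Path | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Corpus:
    """Read a corpus from a call table, optionally attaching contour files.

    Parameters
    ----------
    path
        A delimited call table (TSV default, comma accepted), or a corpus
        directory written by :func:`write_corpus`.
    format
        ``"call_table"`` for a bare table; ``"pitch_dir+table"`` to also read
        one contour file per call from *pitch_dir* (default: ``contours/``
        next to the table), matched by call_id stem.
    aliases
        Optional mapping from canonical column names to the file's names,
        e.g. ``{"individual_id": "emitter"}``.
    """
    path = Path(path)
    if path.is_dir():
        table_path = path / "calls.tsv"
        if pitch_dir is None and (path / "contours").is_dir():
            pitch_dir = path / "contours"
            format = "pitch_dir+table"
    else:
        table_path = path
    if not table_path.exists():
        raise FileNotFoundError(table_path)
    df = pd.read_csv(table_path, sep=None, engine="python")
    df = _resolve_columns(df, aliases)
    if df["call_id"].duplicated().any():
        dupes = df.loc[df["call_id"].duplicated(), "call_id"].tolist()
        raise IntegrityError(f"duplicate call_id(s) in table: {dupes[:5]}")

    contour_of: dict[str, np.ndarray] = {}
    if format == "pitch_dir+table":
        if pitch_dir is None:
            raise ValueError("pitch_dir is required for format 'pitch_dir+table'")
        pitch_dir = Path(pitch_dir)
        for f in sorted(pitch_dir.iterdir()):
            if f.suffix.lower() in (".tsv", ".csv", ".txt", ".pitchtier"):
                contour_of[f.stem] = read_pitch_contour(f)

    calls = []
    for _, row in df.iterrows():
        cid = str(row["call_id"])
        calls.append(
            Call(
                call_id=cid,
                individual_id=str(row["individual_id"]),
                call_type=str(row["call_type"]),
                sequence_id=str(row["sequence_id"]),
                f0_contour=contour_of.get(cid),
                duration=float(row["duration"]) if "duration" in df.columns else float("nan"),
                hnr=float(row["hnr"]) if "hnr" in df.columns else float("nan"),
            )
        )
    return Corpus(calls, metadata={"source": str(path), "filters": []})


def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write a corpus as a call table plus per-call contour TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus.to_frame().to_csv(out_dir / "calls.tsv", sep="\t")
    contour_dir = out_dir / "contours"
    wrote_any = False
    for c in corpus.calls:
        if c.f0_contour is not None:
            contour_dir.mkdir(exist_ok=True)
            np.savetxt(contour_dir / f"{c.call_id}.tsv", c.f0_contour, delimiter="\t")
            wrote_any = True
    if not wrote_any and contour_dir.exists() and not any(contour_dir.iterdir()):
        contour_dir.rmdir()
    return out_dir


# ---------------------------------------------------------------------------
# filtering


def filter_corpus(
    corpus: Corpus,
    allowed_types: Iterable[str] | None = None,
    min_calls: int = 0,
) -> Corpus:
    """Restrict a corpus to the given call types, then to individuals with
    at least *min_calls* calls among those types.

    This mirrors the standard corpus-selection rule for repertoire studies:
    keep the focal call types, then drop under-recorded individuals.
    """
    if min_calls < 0:
        raise ValueError("min_calls must be >= 0")
    calls = list(corpus.calls)
    notes = []
    if allowed_types is not None:
        allowed = set(allowed_types)
        calls = [c for c in calls if c.call_type in allowed]
        notes.append(f"types={sorted(allowed)}")
    if min_calls:
        per_ind: dict[str, int] = {}
        for c in calls:
            per_ind[c.individual_id] = per_ind.get(c.individual_id, 0) + 1
        keep_ind = {i for i, n in per_ind.items() if n >= min_calls}
        calls = [c for c in calls if c.individual_id in keep_ind]
        notes.append(f"min_calls={min_calls}")
    if not calls:
        warnings.warn("filter_corpus produced an empty corpus", stacklevel=2)
    meta = dict(corpus.metadata)
    meta["filters"] = list(meta.get("filters", [])) + notes
    return Corpus(calls, meta)
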