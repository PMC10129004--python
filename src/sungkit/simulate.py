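"""Synthetic SUNG-like call corpora with known ground truth.

The generator emulates the statistical structure of a field-recorded great
ape corpus: a small set of graded call types whose bell-shaped f0 templates
form a continuum of rising pitch, excursion and duration; per-individual
signature effects (a pitch offset, a duration scaling, and idiosyncratic
per-type excursion — an "idiolect"); strong class imbalance; calls grouped
into single-individual vocal sequences dominated by singletons but with a
tail of long sequences; and an injectable sequence-level confound standing
in for the shared soundscape of a recording bout. Every generated quantity
is recorded in a ground-truth table so recovery can be asserted.

The default composition reproduces the call counts per individual and type
of a published 10-individual / 5-type bonobo corpus (1,560 calls), and the
default sequence mix mirrors its sequence-length breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import Call, Corpus, Waveform
from .table import FeatureTable

__all__ = [
    "CallTypeTemplate",
    "SyntheticConfig",
    "GroundTruth",
    "DEFAULT_TEMPLATES",
    "reference_count_matrix",
    "generate_corpus",
    "synthesize_waveform",
    "apply_sequence_confound",
    "leakage_experiment",
]


@dataclass(frozen=True)
class CallTypeTemplate:
    """Raised-cosine f0 template of one call type."""

    name: str
    peak_hz: float        # f0 at the bell's apex
    excursion_hz: float   # apex minus endpoints
    mean_duration_s: float
    duration_sd_s: float
    hnr_db: float
    hnr_sd_db: float


#: a graded five-type continuum: pitch, excursion and duration all rise from
#: peep (P) to scream bark (SCB); SCB harmonicity sits 2.2 dB below bark (B),
#: reflecting its screaming component.
DEFAULT_TEMPLATES = (
    CallTypeTemplate("P", 1200.0, 150.0, 0.10, 0.02, 12.0, 2.0),
    CallTypeTemplate("PY", 1350.0, 300.0, 0.15, 0.03, 11.0, 2.0),
    CallTypeTemplate("SB", 1500.0, 450.0, 0.22, 0.04, 10.0, 2.0),
    CallTypeTemplate("B", 1650.0, 600.0, 0.30, 0.06, 9.0, 2.0),
    CallTypeTemplate("SCB", 1800.0, 750.0, 0.35, 0.07, 6.8, 2.0),
)

_REFERENCE_INDIVIDUALS = (
    "Bolombo", "Busira", "Djanoa", "Hortense", "Jill",
    "Kumbuka", "Lina", "Vifijo", "Zamba", "Zuani",
)

#: calls per individual (rows) and call type (columns) in the reference
#: bonobo corpus used as the default imbalance profile (1,560 calls).
_REFERENCE_COUNTS = {
    "B": (6, 11, 20, 9, 50, 23, 8, 12, 21, 114),
    "P": (27, 18, 18, 26, 24, 35, 24, 20, 43, 20),
    "PY": (24, 34, 49, 50, 89, 26, 18, 61, 56, 36),
    "SB": (17, 5, 36, 8, 112, 25, 23, 51, 55, 50),
    "SCB": (2, 3, 22, 18, 87, 0, 3, 16, 18, 37),
}


def reference_count_matrix() -> pd.DataFrame:
    """The reference corpus composition: individuals x call types (1,560 calls)."""
    df = pd.DataFrame(_REFERENCE_COUNTS, index=list(_REFERENCE_INDIVIDUALS))
    df.index.name = "individual_id"
    df.columns.name = "call_type"
    return df


@dataclass
class SyntheticConfig:
    """Study conditions for the generator. Defaults emulate the reference
    corpus; override fields for controlled experiments."""

    templates: tuple[CallTypeTemplate, ...] = DEFAULT_TEMPLATES
    n_individuals: int = 10
    count_matrix: pd.DataFrame | None = None  # default: reference composition
    n_calls: int | None = None  # alternative to count_matrix: scale reference mix
    individual_pitch_sd: float = 80.0       # Hz, per-individual f0 offset
    individual_duration_sd: float = 0.10    # lognormal sigma of duration scaling
    individual_idiolect_sd: float = 0.05    # lognormal sigma of per-(ind, type) excursion scale
    p_singleton: float = 0.45               # sequence-length mix
    p_double: float = 0.20
    long_extra_mean: float = 2.4            # long sequences: 3 + Poisson(long_extra_mean)
    confound_sd: float = 0.0                # sd of the per-sequence feature shift
    noise_sd: float = 20.0                  # Hz, pointwise contour noise
    contour_points: int = 50
    waveforms: bool = False
    sample_rate: float = 44100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("at least one call-type template is required")
        for t in self.templates:
            if t.mean_duration_s <= 0:
                raise ValueError(f"template {t.name!r} has non-positive duration")
        for name in ("individual_pitch_sd", "individual_duration_sd",
                     "individual_idiolect_sd", "confound_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def counts(self) -> pd.DataFrame:
        """The per-(individual, type) call counts this config generates."""
        if self.count_matrix is not None:
            cm = self.count_matrix.copy()
        else:
            cm = reference_count_matrix()
            cm = cm.iloc[: self.n_individuals]
            cm = cm[[t.name for t in self.templates if t.name in cm.columns]]
            if self.n_calls is not None:
                target = self.n_calls
                raw = cm.to_numpy(dtype=float)
                scaled = raw * target / raw.sum()
                floor = np.floor(scaled).astype(int)
                remainder = (scaled - floor).ravel()
                short = target - floor.sum()
                order = np.argsort(-remainder, kind="stable")[: max(short, 0)]
                flat = floor.ravel()
                flat[order] += 1
                cm = pd.DataFrame(
                    flat.reshape(raw.shape), index=cm.index, columns=cm.columns
                )
        missing = [t.name for t in self.templates if t.name not in cm.columns]
        if missing:
            raise ValueError(f"count matrix lacks template column(s): {missing}")
        return cm


@dataclass
class GroundTruth:
    """Per-call generating parameters, one row per call."""

    per_call: pd.DataFrame  # pitch_offset, duration_scale, sequence_confound

    def confound_of(self, call_ids) -> np.ndarray:
        return self.per_call.loc[list(call_ids), "sequence_confound"].to_numpy()


def synthesize_waveform(
    contour: np.ndarray,
    hnr_db: float,
    rate: float = 44100.0,
    n_harmonics: int = 8,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Additive harmonic synthesis from an f0 contour.

    Harmonics roll off as 1/h; white noise is added at the power ratio
    implied by the requested harmonics-to-noise ratio (dB).
    """
    rng = rng or np.random.default_rng(0)
    duration = contour[-1, 0]
    n = max(int(round(duration * rate)), 2)
    t = np.arange(n) / rate
    f0 = np.interp(t, contour[:, 0], contour[:, 1])
    phase = 2 * np.pi * np.cumsum(f0) / rate
    sig = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        sig += np.sin(h * phase) / h
    p_sig = float(np.mean(sig**2))
    p_noise = p_sig / (10.0 ** (hnr_db / 10.0))
    sig = sig + rng.normal(0.0, np.sqrt(p_noise), size=n)
    return Waveform(samples=sig, rate=rate)


def _draw_sequence_lengths(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    lengths: list[int] = []
    remaining = n
    while remaining > 0:
        u = rng.random()
        if u < cfg.p_singleton:
            L = 1
        elif u < cfg.p_singleton + cfg.p_double:
            L = 2
        else:
            L = 3 + int(rng.poisson(cfg.long_extra_mean))
        lengths.append(min(L, remaining))
        remaining -= lengths[-1]
    return lengths


def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus and its ground truth. Deterministic per config seed.

    Per call: duration = (template mean + jitter) x the individual's duration
    scale; the contour is a raised-cosine bell peaking mid-call at the
    template peak plus the individual's pitch offset, its excursion scaled by
    the individual's idiolect factor for that type, with i.i.d. pointwise
    noise. Calls are grouped (within individual, across types) into vocal
    sequences per the configured length mix, and each sequence receives a
    confound value later applied to features by
    :func:`apply_sequence_confound`.
    """
    rng = np.random.default_rng(config.seed)
    cm = config.counts()
    calls: list[Call] = []
    gt_rows: list[dict] = []
    tpl_by_name = {t.name: t for t in config.templates}

    for ind in cm.index:
        pitch_off = rng.normal(0.0, config.individual_pitch_sd)
        dur_scale = float(np.exp(rng.normal(0.0, config.individual_duration_sd)))
        idiolect = {
            t: float(np.exp(rng.normal(0.0, config.individual_idiolect_sd)))
            for t in cm.columns
        }
        ind_calls: list[tuple[str, Call]] = []
        k = 0
        for typ in cm.columns:
            tpl = tpl_by_name[typ]
            for _ in range(int(cm.loc[ind, typ])):
                # floor at 50 ms: real tonal calls are longer, and two
                # analysis frames must fit in the call
                dur = max(0.05, (tpl.mean_duration_s + rng.normal(0, tpl.duration_sd_s)) * dur_scale)
                t_grid = np.linspace(0.0, dur, config.contour_points)
                peak = tpl.peak_hz + pitch_off
                exc = tpl.excursion_hz * idiolect[typ]
                bell = peak - exc * (1 + np.cos(2 * np.pi * t_grid / dur)) / 2
                f0 = np.maximum(bell + rng.normal(0, config.noise_sd, len(t_grid)), 30.0)
                hnr = tpl.hnr_db + rng.normal(0, tpl.hnr_sd_db)
                contour = np.column_stack([t_grid, f0])
                wav = (
                    synthesize_waveform(contour, hnr, config.sample_rate, rng=rng)
                    if config.waveforms
                    else None
                )
                cid = f"{ind}_c{k:04d}"
                k += 1
                ind_calls.append(
                    (
                        typ,
                        Call(
                            call_id=cid,
                            individual_id=str(ind),
                            call_type=typ,
                            sequence_id="",  # assigned below
                            f0_contour=contour,
                            duration=dur,
                            hnr=hnr,
                            waveform=wav,
                        ),
                    )
                )
        # group this individual's calls (mixed types) into vocal sequences
        order = rng.permutation(len(ind_calls))
        lengths = _draw_sequence_lengths(len(ind_calls), config, rng)
        pos = 0
        for s, L in enumerate(lengths):
            seq_id = f"{ind}_s{s:03d}"
            confound = rng.normal(0.0, config.confound_sd) if config.confound_sd > 0 else 0.0
            for j in order[pos : pos + L]:
                typ, call = ind_calls[j]
                call.sequence_id = seq_id
                gt_rows.append(
                    {
                        "call_id": call.call_id,
                        "pitch_offset": pitch_off,
                        "duration_scale": dur_scale,
                        "sequence_confound": confound,
                    }
                )
            pos += L
        calls.extend(c for _, c in ind_calls)

    corpus = Corpus(calls, metadata={"source": "synthetic", "seed": config.seed})
    gt = GroundTruth(pd.DataFrame(gt_rows).set_index("call_id").loc[corpus.call_ids])
    return corpus, gt


def apply_sequence_confound(table: FeatureTable, ground_truth: GroundTruth) -> FeatureTable:
    """Shift every feature of each call by its sequence's confound value,
    in units of the column's standard deviation.

    This emulates a shared recording soundscape: all calls of a sequence
    move coherently in feature space, by an amount comparable across
    heterogeneous feature scales.
    """
    c = ground_truth.confound_of(table.data.index)
    feats = table.features
    sd = feats.std(axis=0, ddof=1).replace(0.0, 1.0)
    shifted = feats + np.outer(c, sd.to_numpy())
    return table.with_features(shifted)


def leakage_experiment(
    config: SyntheticConfig,
    model=None,
    n_runs: int = 20,
    label: str = "individual_id",
    feature_set: str = "dct",
    seed: int = 0,
    scenarios: tuple[str, ...] = ("default", "fair", "skewed"),
    ga_kwargs: dict | None = None,
) -> dict:
    """Benchmark the same corpus under the three split scenarios.

    Generates a corpus from *config*, extracts one feature set, applies the
    sequence confound, then runs *n_runs* single-split evaluations per
    scenario. Returns per-scenario balanced-accuracy and overlap arrays plus
    the pairwise mean gaps.
    """
    from .classifiers import default_spec
    from .evaluation import repeated_holdout
    from .features import build_feature_table
    from .splitter import scenario_splitter

    if model is None:
        model = default_spec("svm", probability=False)
    cfg = replace(config, seed=config.seed + seed)
    corpus, gt = generate_corpus(cfg)
    table = build_feature_table(corpus, feature_set)
    table = apply_sequence_confound(table, gt)

    results: dict = {"bac": {}, "overlap": {}}
    for scenario in scenarios:
        splitter = scenario_splitter(corpus, scenario, label=label, **(ga_kwargs or {}))
        overlaps = []

        def tracking_splitter(labels, s, _splitter=splitter, _overlaps=overlaps):
            train, test = _splitter(labels, s)
            from .splitter import SplitAssignment, overlap_count

            sa = SplitAssignment(
                pd.Series(np.where(test, "test", "train"), index=corpus.call_ids)
            )
            _overlaps.append(overlap_count(sa, corpus))
            return train, test

        report = repeated_holdout(
            table,
            model,
            label,
            splitter=tracking_splitter,
            n_reps=n_runs,
            seed=seed,
            metrics=("bac",),
        )
        results["bac"][scenario] = report.per_rep["bac"].to_numpy()
        results["overlap"][scenario] = np.asarray(overlaps)
    results["gaps"] = {
        f"{a}-{b}": float(
            np.median(results["bac"][a]) - np.median(results["bac"][b])
        )
        for a in scenarios
        for b in scenarios
        if a != b
    }
    return results
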