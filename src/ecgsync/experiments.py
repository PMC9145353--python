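"""Benchmark harness: the five evaluation experiments on synthetic data.

Each ``run_*`` function builds seeded synthetic sample pairs, runs the
alignment pipeline, and collects per-sample sync delays in a tidy table
keyed by the experimental factors, together with the study's statistical
tests (one-way/two-way ANOVA with Tukey HSD post-hoc, Pearson correlation,
two-sample t-test; alpha = 0.05).

Noise presets name reproducible conditions: "clean" (no noise), "mild"
(electrode motion at 6 dB SNR), "moderate" (electrode motion at 0 dB),
"stress" (electrode motion at -6 dB), and "mixed" (half the pairs at 24 dB,
half at -6 dB electrode motion), so that directional effects -- not any
particular dataset's absolute delays -- are the benchmark's subject.
Electrode motion is the preset noise class because its low-frequency power
overlaps the 2-10 Hz alignment band; baseline wander and muscle artifact
fall almost entirely outside it and are exercised by the noise experiment's
full factorial grid instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .align import estimate_sync_delay, sync_error
from .baseline_dtw import dtw_delay_signals
from .core import PreprocessConfig, SamplePair, Signal, preprocess, resample
from .sqi import QualityUndefinedError, SqiConfig, beat_scores, detect_beats, sample_sqi
from .synth import RhythmSpec, add_noise_kind, generate_record_pair, select_samples

__all__ = [
    "BenchmarkConfig",
    "StatsReport",
    "PRESETS",
    "build_pairs",
    "evaluate_pair",
    "run_duration_experiment",
    "run_sqi_experiment",
    "run_noise_experiment",
    "run_fs_experiment",
    "run_method_comparison",
]

ALPHA = 0.05

# preset -> list of (noise_kind or None, snr_db) conditions cycled over pairs
PRESETS: dict[str, list[tuple[str | None, float]]] = {
    "clean": [(None, 0.0)],
    "mild": [("EM", 6.0)],
    "moderate": [("EM", 0.0)],
    "stress": [("EM", -6.0)],
    "mixed": [("EM", 24.0), ("EM", -6.0)],
}

TABLE_COLUMNS = [
    "record_id", "sample_id", "m_seconds", "sqi_threshold", "noise_kind",
    "snr_db", "fs_hz", "method", "sync_delay_seconds", "sample_sqi", "seed",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Shared settings for one benchmark run."""

    pairs: int = 100
    m_seconds: float = 30.0
    margin: float = 30.0
    fs_native: float = 257.0
    preset: str = "clean"
    rhythm: RhythmSpec = field(default_factory=lambda: RhythmSpec(
        mean_hr=70.0, rr_jitter_sd=0.04, ectopy_rate=0.05))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sqi: SqiConfig = field(default_factory=SqiConfig)
    noise_both_leads: bool = True
    record_duration: float = 600.0
    pairs_per_record: int = 50


@dataclass(frozen=True)
class StatsReport:
    """One statistical test's outcome with optional post-hoc table."""

    test: str
    factors: tuple[str, ...]
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    notes: str = ""
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < self.alpha


def _child_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                 *[int(k) & 0x7FFFFFFF for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def build_pairs(
    n_pairs: int,
    m_seconds: float,
    cfg: BenchmarkConfig,
    seed: int,
) -> list[SamplePair]:
    """Generate clean two-lead records and cut seeded sample pairs from them."""
    pairs: list[SamplePair] = []
    n_records = int(np.ceil(n_pairs / cfg.pairs_per_record))
    for rec in range(n_records):
        rec_seed = _child_seed(seed, 101, rec)
        lead_i, lead_v2, _ = generate_record_pair(
            cfg.record_duration, cfg.rhythm, fs=cfg.fs_native, seed=rec_seed
        )
        take = min(cfg.pairs_per_record, n_pairs - len(pairs))
        pairs.extend(
            select_samples(
                lead_i, lead_v2, m_seconds, take, margin=cfg.margin,
                seed=_child_seed(seed, 202, rec), record_id=f"synth{rec:03d}",
            )
        )
    return pairs


def _noisy_pair(
    pair: SamplePair, kind: str | None, snr_db: float, seed: int,
    both_leads: bool,
) -> SamplePair:
    if kind is None:
        return pair
    search = add_noise_kind(pair.search, kind, snr_db, seed=_child_seed(seed, 1))
    reference = pair.reference
    if both_leads:
        reference = add_noise_kind(
            pair.reference, kind, snr_db, seed=_child_seed(seed, 2)
        )
    return replace(pair, reference=reference, search=search)


def _search_sample_sqi(search: Signal, cfg: BenchmarkConfig) -> float:
    """dSQI of the (noisy) search sample.

    Computed on the resampled signal before the narrow alignment band-pass,
    which would erase the 0-40 Hz morphology the SPWVD template match needs.
    """
    sig = resample(search, cfg.preprocess.target_fs)
    try:
        report = beat_scores(sig, detect_beats(sig), cfg.sqi)
        return sample_sqi(report, cfg.sqi.good_beat_threshold)
    except (QualityUndefinedError, ValueError):
        return 0.0  # unassessable sample: treat as worst quality


def evaluate_pair(
    pair: SamplePair,
    cfg: BenchmarkConfig,
    kind: str | None,
    snr_db: float,
    seed: int,
    method: str = "xcorr",
    with_sqi: bool = False,
    preprocess_cfg: PreprocessConfig | None = None,
) -> dict:
    """Inject noise, preprocess, align, and report one benchmark row."""
    pcfg = preprocess_cfg or cfg.preprocess
    noisy = _noisy_pair(pair, kind, snr_db, seed, cfg.noise_both_leads)
    ref = preprocess(noisy.reference, pcfg)
    search = preprocess(noisy.search, pcfg)
    if method == "xcorr":
        result = estimate_sync_delay(ref, search, mode="pearson")
    elif method == "dtw":
        result = dtw_delay_signals(ref, search)
    else:
        raise ValueError(f"unknown method {method!r}")
    row = {
        "record_id": pair.meta.get("record_id", ""),
        "sample_id": pair.meta.get("sample_id", -1),
        "m_seconds": pair.reference.duration,
        "sqi_threshold": np.nan,
        "noise_kind": kind or "none",
        "snr_db": snr_db if kind else np.nan,
        "fs_hz": pcfg.target_fs,
        "method": method,
        "sync_delay_seconds": sync_error(result, noisy).value_seconds,
        "sample_sqi": np.nan,
        "seed": seed,
    }
    if with_sqi:
        row["sample_sqi"] = _search_sample_sqi(noisy.search, cfg)
    return row


def _preset_conditions(cfg: BenchmarkConfig, i: int) -> tuple[str | None, float]:
    conds = PRESETS[cfg.preset]
    return conds[i % len(conds)]


def one_way_anova(groups: dict, label: str) -> StatsReport:
    """One-way ANOVA across named groups with Tukey HSD pairwise follow-up."""
    keys = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if len(arrays) < 2:
        return StatsReport("one-way ANOVA", (label,), np.nan, np.nan,
                           notes="inapplicable: fewer than two groups")
    f, p = spstats.f_oneway(*arrays)
    tk = spstats.tukey_hsd(*arrays)
    rows = []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            rows.append({
                "group_a": keys[a], "group_b": keys[b],
                "mean_diff": arrays[a].mean() - arrays[b].mean(),
                "p_value": tk.pvalue[a, b],
            })
    return StatsReport("one-way ANOVA", (label,), float(f), float(p),
                       posthoc=pd.DataFrame(rows))


def two_way_anova(df: pd.DataFrame, dv: str, factor_a: str, factor_b: str) -> list[StatsReport]:
    """Two-way ANOVA with interaction; on a significant interaction, simple
    main effects per factor plus Tukey HSD on each factor's margins."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        sub = factor_a if df[factor_a].nunique() >= 2 else factor_b
        rep = one_way_anova(
            {k: g[dv].to_numpy() for k, g in df.groupby(sub)}, sub)
        return [replace(rep, notes="degraded to one-way: single-level factor")]
    model = ols(f"{dv} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = f"C({factor_a}):C({factor_b})"
    reports = [
        StatsReport("two-way ANOVA", (factor_a, factor_b),
                    float(table.loc[inter, "F"]), float(table.loc[inter, "PR(>F)"]),
                    notes="interaction term"),
    ]
    if reports[0].significant:
        # simple main effects: each factor tested within the pooled data
        for fac in (factor_a, factor_b):
            rep = one_way_anova(
                {k: g[dv].to_numpy() for k, g in df.groupby(fac)}, fac)
            reports.append(replace(rep, notes=f"simple main effect of {fac}"))
    else:
        for fac in (factor_a, factor_b):
            main = f"C({fac})"
            reports.append(
                StatsReport("two-way ANOVA main effect", (fac,),
                            float(table.loc[main, "F"]),
                            float(table.loc[main, "PR(>F)"]))
            )
    return reports


def run_duration_experiment(
    durations: Sequence[float] = (10, 20, 30, 40, 50),
    cfg: BenchmarkConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, StatsReport]:
    """Sync delay as a function of reference-sample duration (10-50 s)."""
    if not durations:
        raise ValueError("empty duration grid")
    cfg = cfg or BenchmarkConfig(preset="moderate")
    rows = []
    for gi, m in enumerate(durations):
        pairs = build_pairs(cfg.pairs, m, cfg, _child_seed(seed, 11, gi))
        for i, pair in enumerate(pairs):
            kind, snr = _preset_conditions(cfg, i)
            rows.append(evaluate_pair(pair, cfg, kind, snr,
                                      _child_seed(seed, 12, gi, i)))
    df = pd.DataFrame(rows)[TABLE_COLUMNS]
    report = one_way_anova(
        {m: g["sync_delay_seconds"].to_numpy() for m, g in df.groupby("m_seconds")},
        "m_seconds")
    return df, report


def run_sqi_experiment(
    thresholds: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 1)),
    cfg: BenchmarkConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, StatsReport]:
    """Sync delay after dSQI sample filtering at thresholds 0..1 step 0.1.

    Returns (per-pair table, per-threshold summary, Pearson report).  The
    summary has one row per threshold with the mean/SD delay of retained
    samples and the retaining ratio; a threshold that filters everything
    yields NaN delay and ratio 0, flagged in the summary.
    """
    cfg = cfg or BenchmarkConfig(preset="mixed")
    pairs = build_pairs(cfg.pairs, cfg.m_seconds, cfg, _child_seed(seed, 21))
    rows = []
    for i, pair in enumerate(pairs):
        kind, snr = _preset_conditions(cfg, i)
        rows.append(evaluate_pair(pair, cfg, kind, snr,
                                  _child_seed(seed, 22, i), with_sqi=True))
    df = pd.DataFrame(rows)[TABLE_COLUMNS]
    summary_rows = []
    for thr in thresholds:
        kept = df[df["sample_sqi"] >= thr]
        summary_rows.append({
            "sqi_threshold": thr,
            "mean_delay_s": kept["sync_delay_seconds"].mean() if len(kept) else np.nan,
            "sd_delay_s": kept["sync_delay_seconds"].std() if len(kept) else np.nan,
            "retaining_ratio": len(kept) / len(df),
            "n_retained": len(kept),
            "empty": len(kept) == 0,
        })
    summary = pd.DataFrame(summary_rows)
    ok = summary.dropna(subset=["mean_delay_s"])
    if len(ok) >= 3:
        r, p = spstats.pearsonr(ok["sqi_threshold"], ok["mean_delay_s"])
        report = StatsReport("Pearson correlation", ("sqi_threshold",),
                             float(r), float(p))
    else:
        report = StatsReport("Pearson correlation", ("sqi_threshold",),
                             np.nan, np.nan, notes="too few non-empty thresholds")
    return df, summary, report


def run_noise_experiment(
    kinds: Sequence[str] = ("BW", "EM", "MA"),
    snrs: Sequence[float] = (-6, 0, 6, 12, 18, 24),
    cfg: BenchmarkConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[StatsReport]]:
    """Full factorial noise stress test: kinds x SNR levels, two-way ANOVA."""
    cfg = cfg or BenchmarkConfig()
    rows = []
    for ki, kind in enumerate(kinds):
        for si, snr in enumerate(snrs):
            pairs = build_pairs(cfg.pairs, cfg.m_seconds, cfg,
                                _child_seed(seed, 31, ki, si))
            for i, pair in enumerate(pairs):
                rows.append(evaluate_pair(pair, cfg, kind, snr,
                                          _child_seed(seed, 32, ki, si, i)))
    df = pd.DataFrame(rows)[TABLE_COLUMNS]
    reports = two_way_anova(df, "sync_delay_seconds", "noise_kind", "snr_db")
    return df, reports


def run_fs_experiment(
    rates: Sequence[float] = (150, 200, 250),
    cfg: BenchmarkConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, StatsReport]:
    """Identical pairs aligned at several working sampling rates."""
    cfg = cfg or BenchmarkConfig(preset="moderate")
    for rate in rates:
        if rate < 2 * cfg.preprocess.band_high:
            raise ValueError(
                f"rate {rate} Hz below twice the filter band edge "
                f"{cfg.preprocess.band_high} Hz"
            )
    pairs = build_pairs(cfg.pairs, cfg.m_seconds, cfg, _child_seed(seed, 41))
    rows = []
    for i, pair in enumerate(pairs):
        kind, snr = _preset_conditions(cfg, i)
        noisy_seed = _child_seed(seed, 42, i)
        for rate in rates:
            pcfg = replace(cfg.preprocess, target_fs=float(rate))
            rows.append(evaluate_pair(pair, cfg, kind, snr, noisy_seed,
                                      preprocess_cfg=pcfg))
    df = pd.DataFrame(rows)[TABLE_COLUMNS]
    report = one_way_anova(
        {r: g["sync_delay_seconds"].to_numpy() for r, g in df.groupby("fs_hz")},
        "fs_hz")
    return df, report


def run_method_comparison(
    cfg: BenchmarkConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, StatsReport]:
    """Cross-correlation vs. DTW-on-RR on the same pairs, two-sample t-test."""
    cfg = cfg or BenchmarkConfig(preset="mild")
    pairs = build_pairs(cfg.pairs, cfg.m_seconds, cfg, _child_seed(seed, 51))
    rows = []
    for i, pair in enumerate(pairs):
        kind, snr = _preset_conditions(cfg, i)
        noisy_seed = _child_seed(seed, 52, i)
        for method in ("xcorr", "dtw"):
            rows.append(evaluate_pair(pair, cfg, kind, snr, noisy_seed,
                                      method=method))
    df = pd.DataFrame(rows)[TABLE_COLUMNS]
    a = df.loc[df["method"] == "xcorr", "sync_delay_seconds"].to_numpy()
    b = df.loc[df["method"] == "dtw", "sync_delay_seconds"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        return df, StatsReport("two-sample t-test", ("method",), np.nan, np.nan,
                               notes="inapplicable: fewer than two samples per arm")
    t, p = spstats.ttest_ind(a, b)
    return df, StatsReport("two-sample t-test", ("method",), float(t), float(p))
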