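"""Parameter sweeps and sensitivity analyses.

The experiment layer composes generation, preprocessing and metric
computation into two one-parameter sweeps — temperature (memory span held at
its maximum) and memory span (temperature held at 1) — and quantifies how
sensitively each semantic-distance metric tracks the perturbation:

* Spearman correlation R between the (non-binned) parameter and the metric,
  computed per (prompt x encoding) stratum and averaged, so that consistency
  across prompts and across embedding models is visible;
* Rp, the same correlation after residualizing the *parameter* on the average
  number of words per sentence — the sentence-length confound control;
* binned parameter profiles for inspecting nonmonotonic effects;
* a comparison of the four aggregation methods (mean / min / max / variance)
  by |R|, with the interquartile range across strata as a consistency band.

Memory span is sign-reversed before correlating, so that effects consistent
with formal thought disorder (which is linked to a *lower* span) appear as
positive correlations, mirroring the temperature convention. Statistical
significance is deliberately not computed: it would scale with the number of
simulated narratives, which is a free choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coherence_metrics import AGGREGATIONS, compute_narrative_metrics
from .embeddings import EmbeddingTable, SentenceEncoder
from .generation import GenerationConfig, Narrative, generate_narrative
from .lm_backend import LMBackend
from .preprocessing import preprocess

__all__ = [
    "SweepDesign",
    "CorrelationResult",
    "run_sweep",
    "metrics_table",
    "spearman",
    "residualized_correlation",
    "correlate_sweep",
    "correlation_table",
    "binned_profile",
    "compare_aggregations",
]

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE_GRID = tuple(np.linspace(1.0, 5.0, 9))
DEFAULT_MEMORY_SPAN_GRID = (3, 5, 7, 10, 15, 20, 30, 50, 100, 200)


@dataclass(frozen=True)
class SweepDesign:
    """Design of the two one-parameter sweeps.

    Each sweep varies exactly one parameter over its grid while the other is
    fixed (``fixed_memory_span`` during the temperature sweep,
    ``fixed_temperature`` during the memory-span sweep), with ``n_per_cell``
    replicate narratives per prompt per grid point.
    """

    prompts: tuple[tuple[str, str], ...]  # (prompt_id, prompt_text)
    temperature_grid: tuple[float, ...] = DEFAULT_TEMPERATURE_GRID
    memory_span_grid: tuple[int, ...] = DEFAULT_MEMORY_SPAN_GRID
    n_per_cell: int = 200
    master_seed: int = 0
    fixed_temperature: float = 1.0
    fixed_memory_span: int = 200

    def __post_init__(self) -> None:
        if not self.prompts:
            raise ValueError("at least one prompt is required")
        if not self.temperature_grid or not self.memory_span_grid:
            raise ValueError("parameter grids must be nonempty")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")


def _narrative_seed(master_seed: int, p_idx: int, cell_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([master_seed, p_idx, cell_idx, rep])
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def run_sweep(
    design: SweepDesign,
    backend: LMBackend,
    parameter: str,
    *,
    table: EmbeddingTable | None = None,
    encoder: SentenceEncoder | None = None,
    config_base: GenerationConfig | None = None,
    aggregations: Sequence[str] = AGGREGATIONS,
    exclude_shared: bool = True,
    keep_narratives: bool = False,
) -> pd.DataFrame:
    """Generate, preprocess and score narratives for one sweep.

    Returns a long-format table with one row per (narrative, metric):
    columns ``prompt, parameter, param_value, replicate, seed, metric, level,
    encoding, aggregation, metric_value, mean_words_per_sentence, n_sentences,
    oov_rate``. Deterministic given ``design.master_seed``; per-narrative
    failures are logged and skipped, never aborting the sweep (the count is in
    ``df.attrs['n_failed']``).
    """
    if parameter not in ("temperature", "memory_span"):
        raise ValueError("parameter must be 'temperature' or 'memory_span'")
    if table is None and encoder is None:
        raise ValueError("at least one of table= or encoder= is required")
    base = config_base or GenerationConfig()
    grid = design.temperature_grid if parameter == "temperature" else design.memory_span_grid
    rows: list[dict] = []
    narratives: list[Narrative] = []
    n_failed = 0
    for p_idx, (prompt_id, prompt_text) in enumerate(design.prompts):
        for cell_idx, value in enumerate(grid):
            for rep in range(design.n_per_cell):
                seed = _narrative_seed(design.master_seed, p_idx, cell_idx, rep)
                if parameter == "temperature":
                    cfg = GenerationConfig(
                        **{
                            **base.to_dict(),
                            "temperature": float(value),
                            "memory_span": design.fixed_memory_span,
                            "seed": seed,
                        }
                    )
                else:
                    cfg = GenerationConfig(
                        **{
                            **base.to_dict(),
                            "temperature": design.fixed_temperature,
                            "memory_span": int(value),
                            "seed": seed,
                        }
                    )
                try:
                    narr = generate_narrative(
                        backend, prompt_text, cfg, prompt_id=prompt_id
                    )
                    processed = preprocess(narr.text)
                    metrics = compute_narrative_metrics(
                        processed,
                        prompt_text,
                        table=table,
                        encoder=encoder,
                        aggregations=aggregations,
                        exclude_shared=exclude_shared,
                    )
                except Exception:
                    n_failed += 1
                    logger.exception(
                        "narrative failed: prompt=%s %s=%s rep=%d",
                        prompt_id, parameter, value, rep,
                    )
                    continue
                if keep_narratives:
                    narratives.append(narr)
                for metric, mval in metrics.values.items():
                    parts = metric.split("|")
                    rows.append(
                        {
                            "prompt": prompt_id,
                            "parameter": parameter,
                            "param_value": float(value),
                            "replicate": rep,
                            "seed": seed,
                            "metric": metric,
                            "level": parts[0],
                            "encoding": parts[1] if len(parts) > 1 else "",
                            "aggregation": parts[2] if len(parts) > 2 else "",
                            "metric_value": mval,
                            "mean_words_per_sentence": metrics.mean_words_per_sentence,
                            "n_sentences": metrics.n_sentences,
                            "oov_rate": metrics.oov_rate,
                        }
                    )
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    df.attrs["parameter"] = parameter
    if keep_narratives:
        df.attrs["narratives"] = narratives
    return df


def metrics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Wide per-narrative view: one row per narrative, one column per metric."""
    idx = ["prompt", "param_value", "replicate", "seed"]
    wide = df.pivot_table(index=idx, columns="metric", values="metric_value")
    extra = df.groupby(idx)[["mean_words_per_sentence", "n_sentences"]].first()
    return wide.join(extra).reset_index()


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined marker) when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.spearmanr(x, y).statistic
    return float(r)


def residualized_correlation(
    param: Sequence[float], metric: Sequence[float], confound: Sequence[float]
) -> float:
    """Spearman correlation of the metric with the confound-residualized parameter.

    The *parameter* is OLS-regressed on the confound and its residuals are
    correlated with the metric. A constant confound degrades to the plain
    Spearman correlation (with a warning); residuals that are numerically
    constant (perfect collinearity) yield NaN.
    """
    param = np.asarray(param, dtype=float)
    metric = np.asarray(metric, dtype=float)
    confound = np.asarray(confound, dtype=float)
    if not (len(param) == len(metric) == len(confound)):
        raise ValueError("inputs must have equal length")
    if len(param) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(confound) == 0:
        warnings.warn(
            "constant confound: residualized correlation equals plain Spearman",
            stacklevel=2,
        )
        return spearman(param, metric)
    slope, intercept = np.polyfit(confound, param, 1)
    residuals = param - (intercept + slope * confound)
    if np.allclose(residuals, 0.0, atol=1e-12 * max(1.0, float(np.ptp(param)))):
        return float("nan")
    return spearman(residuals, metric)


def _nanmean(values) -> float:
    arr = np.asarray(list(values), dtype=float)
    finite = arr[~np.isnan(arr)]
    return float(finite.mean()) if finite.size else float("nan")


@dataclass(frozen=True)
class CorrelationResult:
    """Pooled and stratified Spearman correlations for one metric."""

    metric: str
    R: float
    Rp: float
    per_prompt: dict[str, float]
    per_encoder: dict[str, float]
    n: int


def _reverse_if_needed(values: np.ndarray, parameter: str) -> np.ndarray:
    # lower memory span = more impairment, so reverse its sign to make
    # disorder-consistent effects positive
    return -values if parameter == "memory_span" else values


def correlate_sweep(
    df: pd.DataFrame,
    parameter: str,
    *,
    min_stratum: int = 3,
) -> dict[str, CorrelationResult]:
    """Per-metric correlation summaries of a sweep table.

    For each metric, Spearman correlations are computed within each
    (prompt x encoding) stratum and averaged (unweighted) into the headline R;
    Rp residualizes the parameter on mean words per sentence first. Strata
    with fewer than ``min_stratum`` rows are dropped with a warning.
    """
    if "parameter" in df.columns:
        df = df[df["parameter"] == parameter]
    if df.empty:
        raise ValueError(f"table contains no rows for parameter {parameter!r}")
    out: dict[str, CorrelationResult] = {}
    for metric, g in df.groupby("metric"):
        stratum_r: list[tuple[str, str, float, float]] = []
        n_total = 0
        for (prompt, encoding), s in g.groupby(["prompt", "encoding"]):
            s = s.dropna(subset=["metric_value"])
            if len(s) < max(min_stratum, 4):
                logger.warning(
                    "dropping stratum (%s, %s) for %s: only %d rows",
                    prompt, encoding, metric, len(s),
                )
                continue
            x = _reverse_if_needed(s["param_value"].to_numpy(), parameter)
            y = s["metric_value"].to_numpy()
            r = spearman(x, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rp = residualized_correlation(
                    x, y, s["mean_words_per_sentence"].to_numpy()
                )
            stratum_r.append((prompt, encoding, r, rp))
            n_total += len(s)
        if not stratum_r:
            continue
        prompts = sorted({t[0] for t in stratum_r})
        encoders = sorted({t[1] for t in stratum_r})
        per_prompt = {
            p: _nanmean(t[2] for t in stratum_r if t[0] == p) for p in prompts
        }
        per_encoder = {
            e: _nanmean(t[2] for t in stratum_r if t[1] == e) for e in encoders
        }
        out[metric] = CorrelationResult(
            metric=metric,
            R=_nanmean(t[2] for t in stratum_r),
            Rp=_nanmean(t[3] for t in stratum_r),
            per_prompt=per_prompt,
            per_encoder=per_encoder,
            n=n_total,
        )
    return out


def correlation_table(results: Mapping[str, CorrelationResult]) -> pd.DataFrame:
    """Flatten correlation results to a tidy DataFrame."""
    rows = []
    for res in results.values():
        row = {"metric": res.metric, "R": res.R, "Rp": res.Rp, "n": res.n}
        for p, v in res.per_prompt.items():
            row[f"R_prompt_{p}"] = v
        for e, v in res.per_encoder.items():
            row[f"R_encoder_{e}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def binned_profile(
    df: pd.DataFrame,
    parameter: str,
    metric: str,
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Mean metric value per parameter bin, with replicate counts.

    ``bin_edges`` must cover the swept grid; empty bins are kept in the output
    with a NaN mean and zero count (marked, never interpolated).
    """
    if "parameter" in df.columns:
        df = df[df["parameter"] == parameter]
    sub = df[df["metric"] == metric].dropna(subset=["metric_value"])
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    lo, hi = sub["param_value"].min(), sub["param_value"].max()
    if lo < min(bin_edges) or hi > max(bin_edges):
        raise ValueError("bin_edges do not cover the swept grid")
    bins = pd.cut(sub["param_value"], bin_edges, include_lowest=True)
    grouped = sub.groupby(bins, observed=False)["metric_value"]
    out = pd.DataFrame(
        {"bin": grouped.mean().index.astype(str),
         "mean": grouped.mean().to_numpy(),
         "count": grouped.count().to_numpy()}
    )
    return out


def compare_aggregations(
    df: pd.DataFrame,
    parameter: str,
    *,
    min_stratum: int = 4,
) -> pd.DataFrame:
    """Sensitivity of the four aggregation methods, as |R| with an IQR band.

    |Spearman R| is computed per (prompt x encoding x level) stratum for each
    aggregation; the output reports the mean |R| per aggregation and the
    interquartile range across strata as the consistency band.
    """
    if "parameter" in df.columns:
        df = df[df["parameter"] == parameter]
    sub = df[df["aggregation"].isin(AGGREGATIONS)].dropna(subset=["metric_value"])
    rows = []
    for agg, g in sub.groupby("aggregation"):
        abs_r = []
        for _, s in g.groupby(["prompt", "encoding", "level"]):
            if len(s) < min_stratum:
                continue
            x = _reverse_if_needed(s["param_value"].to_numpy(), parameter)
            r = spearman(x, s["metric_value"].to_numpy())
            if not np.isnan(r):
                abs_r.append(abs(r))
        if not abs_r:
            continue
        arr = np.array(abs_r)
        q75, q25 = np.percentile(arr, [75, 25])
        rows.append(
            {
                "aggregation": agg,
                "mean_abs_R": float(arr.mean()),
                "iqr": float(q75 - q25),
                "n_strata": len(arr),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_abs_R", ascending=False).reset_index(drop=True)
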