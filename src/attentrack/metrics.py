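"""Robustness and efficiency measures for adaptive-procedure evaluation.

Given per-track threshold estimates and per-trial interim estimates, this
module computes:

* **bias** — signed error of a single estimate, ``L50_hat - L50`` (positive
  = overestimation);
* **RMSE** — root-mean-square error over runs, with a bootstrap (1000
  replicates of 10,000 resampled estimates each) supplying a mean ± SD;
* **sweat factor** — ``N * sigma^2``: trials times estimate variance, an
  inverse efficiency index (catch trials are excluded from N);
* **normalized efficiency** — ``(1 - p_aborted) / (tau * N * sigma^2)``
  with tau the assumed time per trial (1.5 s one-interval, 2.5 s
  two-tone) and ``p_aborted`` the fraction of aborted attempts;
* **convergence curves** — the across-run SD of the interim estimate at
  each trial, ``sigma(i)``.

``summarize`` rolls these into a tidy per-condition metrics table and a
wide RMSE table (observer conditions x procedures).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .engine import GridResults
from .procedures import DISPLAY_NAMES, make_procedure

__all__ = [
    "bias",
    "rmse",
    "bootstrap_rmse",
    "sweat_factor",
    "normalized_efficiency",
    "convergence_curve",
    "convergence_table",
    "summarize",
    "rmse_table",
]

CONDITION_KEYS = ["procedure", "inattention_type", "concentration", "p_min"]


def bias(estimate, true_l50: float):
    """Signed estimation error in dB; positive = overestimated threshold."""
    return np.asarray(estimate, dtype=float) - true_l50


def rmse(estimates, true_l50: float) -> float:
    """Point RMSE of the estimates against the true threshold."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("rmse requires at least one estimate")
    return float(np.sqrt(np.mean((e - true_l50) ** 2)))


def bootstrap_rmse(estimates, true_l50: float, n_boot: int = 1000,
                   boot_size: int = 10000,
                   rng: Optional[np.random.Generator] = None) -> Tuple[float, float]:
    """Bootstrap mean ± SD of the RMSE.

    Each replicate resamples ``boot_size`` estimates with replacement from
    the pool and takes the RMSE; implemented via multinomial resampling
    counts, which is distributionally identical to drawing the indices
    one by one but far cheaper.
    """
    e = np.asarray(estimates, dtype=float)
    if e.size < 2:
        raise ValueError("bootstrap_rmse requires at least two estimates")
    if rng is None:
        rng = np.random.default_rng()
    sq = (e - true_l50) ** 2
    counts = rng.multinomial(boot_size, np.full(e.size, 1.0 / e.size), size=n_boot)
    reps = np.sqrt(counts @ sq / boot_size)
    return float(reps.mean()), float(reps.std(ddof=1))


def sweat_factor(n_trials: int, sd_estimate: float) -> float:
    """``N * sigma^2`` (dB^2 · trials); N excludes catch trials."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return n_trials * sd_estimate ** 2


def normalized_efficiency(p_aborted: float, tau: float, n_trials: int,
                          sd_estimate: float) -> float:
    """``(1 - p_aborted) / (tau * N * sigma^2)`` in 1/(s · dB^2)."""
    if not 0.0 <= p_aborted <= 1.0:
        raise ValueError("p_aborted must be a probability")
    return (1.0 - p_aborted) / (tau * sweat_factor(n_trials, sd_estimate))


def convergence_curve(interim: np.ndarray) -> np.ndarray:
    """Across-run sample SD (N-1 denominator) of the interim estimate at
    each trial; ``interim`` has shape (n_runs, n_trials)."""
    if interim.ndim != 2 or interim.shape[0] < 2:
        raise ValueError("convergence_curve needs a (runs >= 2, trials) array")
    return interim.std(axis=0, ddof=1)


def convergence_table(grid: GridResults) -> pd.DataFrame:
    """Long-format sigma(i) table: one row per condition x trial."""
    rows = []
    for (proc, typ, conc, pmin), block in grid.interim.items():
        sigma = convergence_curve(block)
        for i, s in enumerate(sigma, start=1):
            rows.append((proc, typ, conc, pmin, i, s))
    return pd.DataFrame(rows, columns=CONDITION_KEYS + ["trial", "sigma"])


def _taus(procedures) -> Dict[str, float]:
    return {key: make_procedure(key).tau for key in procedures}


def summarize(grid: GridResults, seed: Optional[int] = None) -> pd.DataFrame:
    """Per-condition metrics table.

    One row per (procedure, observer) condition with bias summaries
    (median, quartiles), point and bootstrap RMSE, final-trial SD, sweat
    factor, abort fraction and normalized efficiency.  ``seed`` controls
    the bootstrap stream (defaults to the grid's master seed).
    """
    cfg = grid.config
    if seed is None:
        seed = cfg.master_seed
    taus = _taus(cfg.procedures)
    rows = []
    for i, ((proc, typ, conc, pmin), block) in enumerate(grid.interim.items()):
        sub = grid.tracks
        sub = sub[(sub["procedure"] == proc) & (sub["inattention_type"] == typ)
                  & (sub["concentration"] == conc) & (sub["p_min"] == pmin)]
        est = sub["estimate"].to_numpy()
        b = bias(est, cfg.true_l50)
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 7_000_000 + i])))
        point = rmse(est, cfg.true_l50)
        if est.size >= 2:
            bm, bs = bootstrap_rmse(est, cfg.true_l50, cfg.n_bootstrap,
                                    cfg.bootstrap_size, rng)
            sd = float(est.std(ddof=1))
        else:
            bm, bs, sd = point, 0.0, 0.0
        aborted = int(sub["aborted_attempts"].sum())
        attempts = int(sub["attempts"].sum())
        p_aborted = aborted / (aborted + len(sub)) if (aborted + len(sub)) else 0.0
        sf = sweat_factor(cfg.n_trials, sd)
        ne = normalized_efficiency(p_aborted, taus[proc], cfg.n_trials, sd) if sd > 0 else np.inf
        rows.append({
            "procedure": proc, "inattention_type": typ, "concentration": conc,
            "p_min": pmin, "n_runs": len(sub),
            "bias_median": float(np.median(b)),
            "bias_q25": float(np.percentile(b, 25)),
            "bias_q75": float(np.percentile(b, 75)),
            "rmse": point, "rmse_boot_mean": bm, "rmse_boot_sd": bs,
            "sd_final": sd, "sweat_factor": sf,
            "aborted_attempts": aborted, "total_attempts": attempts,
            "p_aborted": p_aborted, "tau": taus[proc],
            "normalized_efficiency": ne,
        })
    return pd.DataFrame(rows)


def rmse_table(metrics: pd.DataFrame, formatted: bool = True) -> pd.DataFrame:
    """Wide RMSE table: rows = (inattention type, concentration, p_min),
    columns = procedures, cells = bootstrap "mean ± SD" strings (or the
    numeric bootstrap mean if ``formatted`` is False)."""
    df = metrics.copy()
    df["procedure"] = df["procedure"].map(lambda k: DISPLAY_NAMES.get(k, k))
    if formatted:
        df["cell"] = df.apply(
            lambda r: f"{r.rmse_boot_mean:.1f} ± {r.rmse_boot_sd:.1f}", axis=1)
    else:
        df["cell"] = df["rmse_boot_mean"]
    wide = df.pivot_table(index=["inattention_type", "concentration", "p_min"],
                          columns="procedure", values="cell", aggfunc="first",
                          sort=False)
    wide.columns.name = None
    return wide.reset_index()
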