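"""Branch-specific acceleration likelihood-ratio tests and GAR calling.

For each element and each designated foreground species (a glider tip), the
null model fits a free global scale lambda on all branches (absorbing
element-wide rate variation); the alternative additionally fits a foreground
scale rho on that species' terminal branch. The LRT statistic is
2(lnL_alt - lnL_null), clipped at zero, and the one-sided acceleration
p-value uses the half-chi-square boundary convention: rho = 1 lies on the
boundary of the one-sided alternative rho > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..msa import OrthologueAlignment
from .likelihood import LikelihoodEngine
from .model import PhyloModel

__all__ = [
    "AccelerationResult",
    "test_acceleration",
    "results_table",
    "call_gars",
    "conservation_scores",
    "write_wig",
]

_LOG_BOUND = 7.0  # bounds on log-lambda and log-rho
_ALT_STARTS = ((0.0, 0.0), (0.0, np.log(4.0)), (0.0, -np.log(4.0)))


@dataclass
class AccelerationResult:
    element_id: str
    foreground_branch: str
    lnl_null: float
    lnl_alt: float
    lambda_hat: float
    rho_hat: float
    lrt: float
    p_one_sided: float
    is_gar: bool
    untestable: bool = False


def _informative(engine: LikelihoodEngine) -> bool:
    """True if any site pattern shows more than one distinct base."""
    for col in engine.patterns.T:
        if len({int(b) for b in col if b < 4}) > 1:
            return True
    return False


def _fit_null(engine: LikelihoodEngine) -> tuple[float, float]:
    """Maximize lnL over log-lambda with rho fixed at 1."""
    res = optimize.minimize_scalar(
        lambda x: -engine.loglik(np.exp(x)),
        bounds=(-_LOG_BOUND, _LOG_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x)), float(-res.fun)


def _fit_alt(
    engine: LikelihoodEngine, extra_starts: tuple[tuple[float, float], ...] = ()
) -> tuple[float, float, float]:
    """Maximize lnL over (log-lambda, log-rho) from fixed multi-starts.

    Ties are broken by higher lnL, then smaller |log rho|.
    """
    best = None
    for start in _ALT_STARTS + tuple(extra_starts):
        res = optimize.minimize(
            lambda v: -engine.loglik(np.exp(v[0]), np.exp(v[1])),
            x0=np.asarray(start),
            method="L-BFGS-B",
            bounds=[(-_LOG_BOUND, _LOG_BOUND)] * 2,
        )
        cand = (-res.fun, -abs(res.x[1]), float(res.x[0]), float(res.x[1]))
        if best is None or cand[:2] > best[:2]:
            best = cand
    lnl, _, loglam, logrho = best
    return float(np.exp(loglam)), float(np.exp(logrho)), float(lnl)


def test_acceleration(
    msa: OrthologueAlignment,
    model: PhyloModel,
    foreground: str,
    alpha: float = 0.05,
) -> AccelerationResult:
    """One-sided LRT for substitution-rate acceleration on one tip branch."""
    if foreground not in msa.rows or foreground not in model.tree.tip_index:
        return AccelerationResult(
            msa.element_id, foreground, np.nan, np.nan, np.nan, np.nan,
            np.nan, np.nan, False, untestable=True,
        )
    engine = LikelihoodEngine(msa, model, foreground=foreground)
    if not _informative(engine):
        # no substitutions at all: rho is unidentifiable, the LRT carries no
        # signal (avoids a spurious boundary artifact at the lambda bound)
        lam0, lnl0 = _fit_null(engine)
        return AccelerationResult(
            msa.element_id, foreground, lnl0, lnl0, lam0, 1.0, 0.0, 0.5, False
        )
    lambda_hat, lnl_null = _fit_null(engine)
    # seed the alternative with the null optimum too, so lnL_alt >= lnL_null
    lam_a, rho_a, lnl_alt = _fit_alt(
        engine, extra_starts=((np.log(lambda_hat), 0.0),)
    )
    if lnl_alt < lnl_null:  # numerically identical optima
        lam_a, rho_a, lnl_alt = lambda_hat, 1.0, lnl_null
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    tail = stats.chi2.sf(lrt, df=1)
    p = 0.5 * tail if rho_a > 1.0 else 1.0 - 0.5 * tail
    return AccelerationResult(
        msa.element_id, foreground, lnl_null, lnl_alt,
        lam_a, rho_a, lrt, float(p), bool(p < alpha),
    )


def results_table(results: list[AccelerationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": pd.Series([r.element_id for r in results], dtype=str),
            "species": pd.Series([r.foreground_branch for r in results], dtype=str),
            "lnL_null": pd.Series([r.lnl_null for r in results], dtype=float),
            "lnL_alt": pd.Series([r.lnl_alt for r in results], dtype=float),
            "lambda_hat": pd.Series([r.lambda_hat for r in results], dtype=float),
            "rho_hat": pd.Series([r.rho_hat for r in results], dtype=float),
            "LRT": pd.Series([r.lrt for r in results], dtype=float),
            "p": pd.Series([r.p_one_sided for r in results], dtype=float),
            "untestable": pd.Series([r.untestable for r in results], dtype=bool),
        }
    )


def call_gars(
    results: pd.DataFrame, alpha: float = 0.05, correction: str = "none"
) -> dict:
    """Per-species GAR sets and their overlap structure.

    ``results`` needs columns element_id, species, p. With ``correction=
    "BH"`` the Benjamini-Hochberg adjustment is applied within each species'
    family of tests (each species has its own accelerated-region list).
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    df = results.dropna(subset=["p"]).copy()
    if correction == "BH":
        df["q"] = df.groupby("species")["p"].transform(
            lambda p: stats.false_discovery_control(p, method="bh")
        )
        crit = "q"
    else:
        df["q"] = np.nan
        crit = "p" if correction == "none" else "q"
    species = sorted(df["species"].unique())
    per_species = {
        sp: set(df.loc[(df["species"] == sp) & (df[crit] < alpha), "element_id"])
        for sp in species
    }
    union = set().union(*per_species.values()) if per_species else set()
    pairwise = {
        (a, b): per_species[a] & per_species[b]
        for i, a in enumerate(species)
        for b in species[i + 1 :]
    }
    shared_any_pair = set().union(*pairwise.values()) if pairwise else set()
    three_way = (
        set.intersection(*per_species.values()) if len(per_species) >= 3 else set()
    )
    return {
        "alpha": alpha,
        "correction": correction,
        "per_species": per_species,
        "union": union,
        "pairwise": pairwise,
        "shared_any_pair": shared_any_pair,
        "three_way": three_way,
        "counts": {
            **{f"n_{sp}": len(v) for sp, v in per_species.items()},
            "n_union": len(union),
            "n_shared_any_pair": len(shared_any_pair),
            "n_three_way": len(three_way),
        },
        "table": df,
    }


def conservation_scores(
    msa: OrthologueAlignment, model: PhyloModel, window: int = 1
) -> np.ndarray:
    """Per-column (or per-window) conservation/acceleration score track.

    Each column is tested with an all-branch scale LRT against lambda = 1;
    the score is -log10(p) with positive sign for estimated slowdown
    (lambda_hat < 1, conservation) and negative for speedup. Columns carrying
    no information score 0.
    """
    if msa.length < window:
        raise ValueError("alignment shorter than window")
    engine = LikelihoodEngine(msa, model)
    pattern_score = np.empty(engine.n_patterns)
    for k in range(engine.n_patterns):
        pattern_score[k] = _column_score(engine, k)
    scores = pattern_score[engine.column_pattern]
    if window > 1:
        kernel = np.ones(window) / window
        scores = np.convolve(scores, kernel, mode="same")
    return scores


def _column_score(engine: LikelihoodEngine, pattern_idx: int) -> float:
    def negll(x: float) -> float:
        return -float(engine.pattern_logliks(np.exp(x))[pattern_idx])

    lnl0 = -negll(0.0)
    res = optimize.minimize_scalar(
        negll, bounds=(-_LOG_BOUND, _LOG_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(np.exp(res.x))
    lrt = max(0.0, 2.0 * (-res.fun - lnl0))
    if lrt <= 0.0:
        return 0.0
    p = float(stats.chi2.sf(lrt, df=1))
    magnitude = -np.log10(max(p, 1e-300))
    return magnitude if lam_hat < 1.0 else -magnitude


def write_wig(
    scores: np.ndarray,
    msa: OrthologueAlignment,
    ref_interval,
    path,
    track_name: str = "conservation",
) -> None:
    """Write scores on reference coordinates as a variableStep wiggle track.

    Only columns where the reference row has a base are emitted; positions
    are 1-based per wiggle convention.
    """
    ref = msa.reference_row()
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        fh.write(f"variableStep chrom={ref_interval.chrom}\n")
        pos = ref_interval.start
        for col, ch in enumerate(ref):
            if ch != "-":
                fh.write(f"{pos + 1}\t{scores[col]:.4f}\n")
                pos += 1
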