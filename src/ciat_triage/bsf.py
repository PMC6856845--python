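"""Binomial Survivor Function (BSF) promiscuity score.

The BSF treats screening as a binomial experiment: a compound tested in
``N`` assays with overall hit rate ``h`` should be active about ``N*h``
times by chance.  The score is the negative decimal logarithm of the
binomial upper-tail probability of observing at least the compound's
active count::

    pBSF = -log10( P(X >= A) ),   X ~ Binomial(N, h)

A compound with pBSF >= 2 (at most a 1 % chance that its record arose by
chance) is classified as interfering/promiscuous.  The score is
structure-independent but undefined for compounds never tested: in
leave-one-assay-out evaluation those are flagged unpredictable.

The tail is evaluated with a log-sum-exp over log-binomial terms, so small
hit rates and large test counts do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ScreeningHistory",
    "pooled_hit_rate",
    "screening_history",
    "pbsf",
    "classify_bsf",
    "bsf_loao",
    "subsample_assay_fraction",
    "BSF_CUTOFF",
]

BSF_CUTOFF = 2.0
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ScreeningHistory:
    """Per-compound screening record: tested in N distinct assays, active in A."""

    compound_id: str
    n_tested: int
    n_active: int

    def __post_init__(self) -> None:
        if self.n_tested < 0 or self.n_active < 0:
            raise ValueError("counts must be non-negative")
        if self.n_active > self.n_tested:
            raise ValueError("active count cannot exceed tested count")


def pooled_hit_rate(
    results: pd.DataFrame, assays: Iterable[str] | None = None
) -> float:
    """Hit rate pooled over the considered primary assays.

    ``h`` = active results / all conclusive results.  Equals the mean of
    per-assay hit rates weighted by assay size.
    """
    df = results
    if assays is not None:
        df = df[df["assay_id"].isin(set(assays))]
    df = df[df["activity_flag"].isin(["active", "inactive"])]
    if len(df) == 0:
        raise ValueError("no results to pool a hit rate from")
    return float((df["activity_flag"] == "active").mean())


def screening_history(
    results: pd.DataFrame, assays: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-compound (N tested, A active) counts over distinct assays.

    Replicates within one assay collapse to a single (tested, active?) pair
    before counting; "active" means active in at least one replicate.
    Returns ``compound_id, n_tested, n_active``.
    """
    df = results
    if assays is not None:
        df = df[df["assay_id"].isin(set(assays))]
    df = df[df["activity_flag"].isin(["active", "inactive"])]
    if len(df) == 0:
        return pd.DataFrame(columns=["compound_id", "n_tested", "n_active"])
    per_assay = (
        df.assign(_active=df["activity_flag"] == "active")
        .groupby(["compound_id", "assay_id"], sort=True)["_active"]
        .any()
    )
    counts = per_assay.groupby("compound_id").agg(["count", "sum"])
    out = counts.reset_index()
    out.columns = ["compound_id", "n_tested", "n_active"]
    out["n_active"] = out["n_active"].astype(int)
    return out


def _log_binom_tail(A: int, N: int, h: float) -> float:
    """log of P(X >= A) for X ~ Binomial(N, h), computed in log space."""
    if A <= 0:
        return 0.0
    if h >= 1.0:
        return 0.0
    if h <= 0.0:
        return -math.inf
    a = np.arange(A, N + 1)
    log_terms = (
        gammaln(N + 1)
        - gammaln(a + 1)
        - gammaln(N - a + 1)
        + a * math.log(h)
        + (N - a) * math.log1p(-h)
    )
    return float(logsumexp(log_terms))


def pbsf(A: int, N: int, h: float, decibel: bool = False) -> float:
    """Binomial survivor function score.

    Parameters
    ----------
    A, N:
        Screens active / screens tested (A <= N, distinct assays).
    h:
        Pooled hit rate in [0, 1].
    decibel:
        If True, return the literal decibel-style ``-10*log10(tail)``
        variant; by default the score is ``-log10(tail)`` so that the
        classification cutoff of 2 corresponds to a 1 % chance.

    ``pbsf(0, N, h) = 0`` for every N and h (the tail probability is 1),
    and ``pbsf(N, N, h) = -N*log10(h)`` exactly.
    """
    A = int(A)
    N = int(N)
    if A < 0 or N < 0:
        raise ValueError("A and N must be non-negative")
    if A > N:
        raise ValueError(f"A={A} exceeds N={N}")
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"hit rate must be in [0, 1], got {h}")
    if A == N and A > 0 and h > 0.0:
        # single-term tail: use the closed form, exact in log10
        score = -A * math.log10(h)
    else:
        log_tail = _log_binom_tail(A, N, h)
        score = -log_tail / _LN10
    score = max(score, 0.0) + 0.0  # clamp tiny negative rounding, avoid -0.0
    return 10.0 * score if decibel else score


def pbsf_scores(
    n_active: Sequence[int], n_tested: Sequence[int], h: float, decibel: bool = False
) -> np.ndarray:
    """Vectorized :func:`pbsf` over per-compound histories."""
    return np.array(
        [pbsf(a, n, h, decibel=decibel) for a, n in zip(n_active, n_tested)]
    )


def classify_bsf(score: float, cutoff: float = BSF_CUTOFF) -> str:
    """CIAT iff the score reaches the cutoff (default pBSF >= 2)."""
    return "CIAT" if score >= cutoff else "NCIAT"


def bsf_loao(
    results: pd.DataFrame,
    held_out_assay: str,
    assays: Iterable[str] | None = None,
    cutoff: float = BSF_CUTOFF,
    decibel: bool = False,
) -> pd.DataFrame:
    """Score the held-out assay's compounds from all other assays' history.

    ``assays`` is the considered assay universe (default: every assay in
    ``results``); the held-out assay is removed from it before computing
    histories and the pooled hit rate.  Compounds tested in the held-out
    assay but nowhere else have no history (N=0) and are flagged
    unpredictable.

    Returns ``compound_id, n_tested, n_active, pbsf, bsf_class,
    predictable`` for every compound tested in the held-out assay.
    """
    universe = set(assays) if assays is not None else set(results["assay_id"])
    rest = universe - {held_out_assay}
    if not rest:
        raise ValueError("need at least one assay besides the held-out one")
    held_ids = results.loc[
        results["assay_id"] == held_out_assay, "compound_id"
    ].unique()
    hist = screening_history(results, assays=rest)
    hist = hist.set_index("compound_id").reindex(held_ids)
    hist[["n_tested", "n_active"]] = hist[["n_tested", "n_active"]].fillna(0)
    hist = hist.astype({"n_tested": int, "n_active": int})
    h = pooled_hit_rate(results, assays=rest)
    scores = pbsf_scores(hist["n_active"], hist["n_tested"], h, decibel=decibel)
    out = hist.reset_index()
    out["pbsf"] = scores
    out["bsf_class"] = [classify_bsf(s, cutoff=cutoff) for s in scores]
    out["predictable"] = out["n_tested"] > 0
    return out


def subsample_assay_fraction(
    results: pd.DataFrame,
    fraction: float,
    seed: int,
    base_assays: Iterable[str],
    pool_assays: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Restrict results to the base assays plus a random slice of the pool.

    The artefact-linked primary assays (``base_assays``) are always kept;
    ``round(fraction * len(pool))`` assays are drawn from the remaining
    pool without replacement (seeded).  ``fraction`` must lie in (0, 1];
    1.0 keeps everything.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    base = set(base_assays)
    if pool_assays is None:
        pool = sorted(set(results["assay_id"]) - base)
    else:
        pool = sorted(set(pool_assays) - base)
    n_pick = int(round(fraction * len(pool)))
    rng = np.random.default_rng(seed)
    picked = set(rng.choice(pool, size=n_pick, replace=False)) if n_pick else set()
    keep = base | picked
    return results[results["assay_id"].isin(keep)].copy()
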