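"""Hub identification, cumulative strength-distribution fits, and meta-map overlap.

The complementary cumulative distribution P(S >= x) of nodal strengths is
fit, on log scale, to three candidate families:

    power law                  log p = c + (alpha - 1) log x
    exponential                log p = c - x / x_c
    truncated power law        log p = c + (alpha - 1) log x - x / x_c

by ordinary least squares (matching the log-log presentation of such
distributions); goodness-of-fit is R^2 on log p and the best family is the
R^2 argmax. A long-tailed broad-scale (truncated power law) winner indicates
that connectivity concentrates on a small set of hub nodes. Hubs are the
top-n nodes by strength (n = 20 by default); overlap with binary
meta-analytic node masks is quantified by the Dice coefficient
2|A∩B| / (|A| + |B|), optionally restricted to one hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

FAMILIES = ("power_law", "exponential", "truncated_power_law")


@dataclass
class FamilyFit:
    params: dict[str, float]
    r2: float


@dataclass
class DistributionFit:
    fits: dict[str, FamilyFit] = field(default_factory=dict)

    @property
    def best_family(self) -> str:
        return max(FAMILIES, key=lambda f: self.fits[f].r2)

    def r2(self, family: str) -> float:
        return self.fits[family].r2


@dataclass
class HubSet:
    state_id: int
    node_ids: np.ndarray     # descending strength
    strengths: np.ndarray
    n_hubs: int

    def __post_init__(self) -> None:
        if len(self.node_ids) != self.n_hubs:
            raise ValueError("hub set size mismatch")
        if np.any(np.diff(self.strengths) > 0):
            raise ValueError("hub strengths must be non-increasing")

    def mask(self, n_nodes: int) -> np.ndarray:
        m = np.zeros(n_nodes, dtype=bool)
        m[self.node_ids] = True
        return m


def cumulative_distribution(strengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complementary cumulative distribution P(S >= x) at observed unique values."""
    s = np.asarray(strengths, dtype=float).ravel()
    s = s[s > 0]
    if s.size < 5:
        raise ValueError("need at least 5 positive strengths")
    x = np.unique(s)
    p = np.array([(s >= xi).mean() for xi in x])
    return x, p


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def fit_families(x: np.ndarray, p: np.ndarray) -> DistributionFit:
    """Least-squares fits of log p against the three model forms."""
    x = np.asarray(x, float)
    p = np.asarray(p, float)
    if np.any(x <= 0) or np.any(p <= 0):
        raise ValueError("x and p must be positive")
    if np.unique(x).size <= 2:
        raise ValueError("degenerate input: need more than 2 distinct x values")
    logx = np.log(x)
    logp = np.log(p)
    ones = np.ones_like(x)

    fits: dict[str, FamilyFit] = {}

    coef, r2 = _ols_r2(np.column_stack([ones, logx]), logp)
    fits["power_law"] = FamilyFit(params=dict(alpha=coef[1] + 1.0), r2=r2)

    coef, r2 = _ols_r2(np.column_stack([ones, x]), logp)
    xc = -1.0 / coef[1] if coef[1] < 0 else np.inf
    fits["exponential"] = FamilyFit(params=dict(x_cutoff=xc), r2=r2)

    coef, r2 = _ols_r2(np.column_stack([ones, logx, x]), logp)
    xc = -1.0 / coef[2] if coef[2] < 0 else np.inf
    fits["truncated_power_law"] = FamilyFit(
        params=dict(alpha=coef[1] + 1.0, x_cutoff=xc), r2=r2
    )
    return DistributionFit(fits=fits)


def fit_strength_distribution(strengths: np.ndarray) -> DistributionFit:
    """Convenience: CCDF + family fits from a raw strength vector."""
    x, p = cumulative_distribution(strengths)
    return fit_families(x, p)


def sample_truncated_power_law(
    alpha: float, x_cutoff: float, n: int, rng: np.random.Generator, x_min: float = 1.0
) -> np.ndarray:
    """Draw samples with density ~ x^(alpha-2) exp(-x/x_c) on [x_min, inf).

    (The CCDF of such samples behaves like x^(alpha-1) exp(-x/x_c) up to slowly
    varying factors.) Rejection sampling from the exponential envelope.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        if alpha > 2.0:
            raise ValueError("exponential envelope requires alpha <= 2")
        cand = x_min + rng.exponential(x_cutoff, size=2 * (n - filled))
        accept = rng.random(cand.size) < (cand / x_min) ** (alpha - 2.0)
        kept = cand[accept]
        take = min(kept.size, n - filled)
        out[filled : filled + take] = kept[:take]
        filled += take
    return out


def extract_hubs(
    strengths: np.ndarray, n_hubs: int = 20, state_id: int = 0
) -> HubSet:
    """Top-n nodes by nodal strength; boundary ties go to the smaller node id."""
    s = np.asarray(strengths, dtype=float).ravel()
    if s.size < n_hubs:
        raise ValueError(f"need at least {n_hubs} nodes, got {s.size}")
    # sort by (-strength, node_id): deterministic tie-break toward smaller id
    order = np.lexsort((np.arange(s.size), -s))
    top = order[:n_hubs]
    return HubSet(state_id=state_id, node_ids=top, strengths=s[top], n_hubs=n_hubs)


def dice_overlap(
    hub_mask: np.ndarray,
    meta_mask: np.ndarray,
    hemisphere_mask: np.ndarray | None = None,
) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binary node masks."""
    a = np.asarray(hub_mask).astype(bool)
    b = np.asarray(meta_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have equal length")
    if hemisphere_mask is not None:
        h = np.asarray(hemisphere_mask).astype(bool)
        if h.shape != a.shape:
            raise ValueError("hemisphere mask length mismatch")
        a, b = a[h], b[h]
    denom = a.sum() + b.sum()
    if denom == 0:
        logger.warning("both masks empty after restriction; dice defined as 0")
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
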