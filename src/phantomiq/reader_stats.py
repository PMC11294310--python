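"""Reader-study statistics and a synthetic Likert-score generator.

Covers the statistics used for subjective image-quality reading sessions:
paired Wilcoxon signed-rank tests with Bonferroni correction for the
comparisons between reconstructions, and Krippendorff's alpha with an
ordinal distance metric for inter-reader agreement, with the customary
interpretation bands (poor/fair/moderate/substantial/excellent at
0.2/0.4/0.6/0.8).

Because no reader data are deposited, the module also ships a latent-
Gaussian ordinal simulator: each (reconstruction, criterion, anatomic
level) cell has a target median and IQR taken from the published summary
table; a reader's latent opinion is the cell mean plus a persistent
reader bias plus residual noise, rounded and clipped to the 1-5 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "AgreementResult",
    "LikertDataset",
    "wilcoxon_paired",
    "krippendorff_alpha",
    "interpret_alpha",
    "synth_likert",
    "load_likert_profile",
    "ALPHA_BANDS",
]

# Interpretation cut points: (upper bound, label], lowest band closed at 0.
ALPHA_BANDS: tuple[tuple[float, str], ...] = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "excellent"),
)

_EXACT_N_MAX = 25

CRITERIA = ("noise", "delineation", "overall")
LEVELS = ("popliteal", "btk")


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired signed-rank test outcome with Bonferroni adjustment."""

    statistic: float  # W+ (sum of positive ranks after discarding zeros)
    p_value: float
    p_adjusted: float
    n_nonzero: int
    m_comparisons: int
    method: str  # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p of the signed-rank sum, conditional on |d| ranks.

    Enumerates the 2^n equiprobable sign assignments by a convolution over
    doubled (hence integer) midranks; ties in |d| are therefore handled
    exactly.  The null distribution is symmetric, so the two-sided p is
    twice the smaller tail, capped at 1.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2.0 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_paired(
    x: Sequence[float],
    y: Sequence[float],
    m_comparisons: int = 1,
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test with Bonferroni correction.

    Zero differences are discarded (classical Wilcoxon convention).  For
    up to 25 non-zero pairs the exact conditional null distribution is
    used (valid under ties); beyond that, the tie-corrected normal
    approximation.  All differences zero is reported as a degenerate
    result with p = 1.  The adjusted p is ``min(1, m * p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in shape: {x.shape} vs {y.shape}")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, p_adjusted=1.0,
            n_nonzero=0, m_comparisons=m_comparisons, method="degenerate",
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
        p = float(res.pvalue)
        method = "normal"
    return WilcoxonResult(
        statistic=w_plus,
        p_value=p,
        p_adjusted=min(1.0, m_comparisons * p),
        n_nonzero=n,
        m_comparisons=m_comparisons,
        method=method,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Krippendorff's alpha with its interpretation band."""

    alpha: float
    band: str | None
    n_units: int
    n_raters: int
    degenerate: bool = False


def krippendorff_alpha(ratings: np.ndarray | pd.DataFrame) -> AgreementResult:
    """Krippendorff's alpha for ordinal ratings, units x raters.

    Missing ratings are NaN.  Built on the coincidence matrix: each unit
    with ``m >= 2`` ratings contributes each ordered pair of its ratings
    with weight ``1/(m-1)``; with ordinal distances
    ``delta(c,k) = (sum_{g=c..k} n_g - (n_c + n_k)/2)**2`` the coefficient
    is ``1 - (n-1) * sum o_ck delta / sum n_c n_k delta`` over ``c < k``.
    Data in a single category leave chance disagreement undefined; alpha
    is then NaN with the degenerate flag set.
    """
    values = np.asarray(
        ratings.values if isinstance(ratings, pd.DataFrame) else ratings, dtype=float
    )
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("ratings must be a 2D units x raters table with >= 2 raters")
    cats = np.unique(values[~np.isnan(values)])
    if cats.size == 0:
        raise ValueError("no ratings present")
    index = {c: i for i, c in enumerate(cats)}
    k = cats.size
    coincidence = np.zeros((k, k))
    usable_units = 0
    for row in values:
        present = row[~np.isnan(row)]
        m = present.size
        if m < 2:
            continue
        usable_units += 1
        idx = [index[v] for v in present]
        for a in idx:
            for b in idx:
                coincidence[a, b] += 1.0 / (m - 1)
        for a in idx:  # remove self-pairs counted above
            coincidence[a, a] -= 1.0 / (m - 1)
    if usable_units == 0:
        raise ValueError("no unit has two or more ratings; agreement undefined")
    n_c = coincidence.sum(axis=1)
    n_tot = n_c.sum()
    if k == 1:
        return AgreementResult(
            alpha=float("nan"), band=None, n_units=usable_units,
            n_raters=values.shape[1], degenerate=True,
        )
    # ordinal squared distances from the coincidence marginals
    delta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            span = n_c[i : j + 1].sum()
            delta[i, j] = delta[j, i] = (span - (n_c[i] + n_c[j]) / 2.0) ** 2
    d_obs = sum(
        coincidence[i, j] * delta[i, j] for i in range(k) for j in range(i + 1, k)
    )
    d_exp = sum(n_c[i] * n_c[j] * delta[i, j] for i in range(k) for j in range(i + 1, k))
    if d_exp == 0:
        return AgreementResult(
            alpha=float("nan"), band=None, n_units=usable_units,
            n_raters=values.shape[1], degenerate=True,
        )
    alpha = 1.0 - (n_tot - 1.0) * d_obs / d_exp
    return AgreementResult(
        alpha=float(alpha),
        band=interpret_alpha(alpha),
        n_units=usable_units,
        n_raters=values.shape[1],
    )


def interpret_alpha(alpha: float) -> str:
    """Map an agreement coefficient to its interpretation band.

    Bands are half-open upward: poor up to and including 0.2, then fair,
    moderate, substantial, excellent up to 1.0.  Values below zero mean
    systematic disagreement and fall in "poor".
    """
    if math.isnan(alpha):
        raise ValueError("alpha is undefined")
    if not -1.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [-1, 1], got {alpha}")
    for upper, label in ALPHA_BANDS:
        if alpha <= upper:
            return label
    return ALPHA_BANDS[-1][1]  # pragma: no cover - alpha == 1 handled above


def load_likert_profile() -> pd.DataFrame:
    """Packaged per-cell score targets (median and IQR bounds).

    Columns: kernel, qir, criterion, level, median, iqr_lo, iqr_hi —
    one row for each of the 9 reconstructions x 3 criteria x 2 anatomic
    levels of the reading session.
    """
    with resources.files("phantomiq.data").joinpath("likert_profile.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class LikertDataset:
    """Long-format ordinal scores of a (possibly synthetic) reading session.

    Columns: reader, patient, kernel, qir, criterion, level, score.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = self.table["score"]
        if not scores.between(1, 5).all() or (scores != scores.round()).any():
            raise ValueError("scores must be integers in 1..5")

    def ratings_matrix(self, criterion: str, level: str) -> np.ndarray:
        """Units x raters matrix (units = patient x reconstruction cells)."""
        sub = self.table[
            (self.table["criterion"] == criterion) & (self.table["level"] == level)
        ]
        pivot = sub.pivot_table(
            index=["patient", "kernel", "qir"], columns="reader", values="score"
        )
        return pivot.values.astype(float)

    def paired_scores(
        self, criterion: str, level: str, recon_a: tuple[str, int], recon_b: tuple[str, int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per (reader, patient) score pairs for two reconstructions."""
        sub = self.table[
            (self.table["criterion"] == criterion) & (self.table["level"] == level)
        ]
        pivot = sub.pivot_table(
            index=["reader", "patient"], columns=["kernel", "qir"], values="score"
        )
        return pivot[recon_a].values, pivot[recon_b].values

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LikertDataset":
        return cls(table=pd.read_csv(path), provenance={"source": str(path)})


def synth_likert(
    profile: pd.DataFrame | None = None,
    *,
    n_patients: int = 20,
    n_readers: int = 3,
    residual_scale: float = 1.0,
    reader_bias_sd: float = 0.15,
    seed: int = 0,
) -> LikertDataset:
    """Simulate a reading session from per-cell median/IQR targets.

    Latent-Gaussian ordinal model: for cell mean ``mu`` (the target
    median) and latent spread ``sigma`` matched to the target IQR
    (``sigma = residual_scale * max(iqr_width/1.349, 0.25)``), reader
    ``r`` scores patient ``p`` as
    ``clip(round(mu + bias_r + eps), 1, 5)`` with ``eps ~ N(0, sigma)``
    and ``bias_r ~ N(0, reader_bias_sd)`` drawn once per reader.  With
    ``residual_scale=0`` and ``reader_bias_sd=0`` every cell reproduces
    its target median exactly.
    """
    if profile is None:
        profile = load_likert_profile()
    required = {"kernel", "qir", "criterion", "level", "median", "iqr_lo", "iqr_hi"}
    missing = required - set(profile.columns)
    if missing:
        raise ValueError(f"profile missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    biases = rng.normal(0.0, reader_bias_sd, size=n_readers) if reader_bias_sd > 0 else np.zeros(n_readers)
    rows = []
    for _, cell in profile.iterrows():
        width = float(cell["iqr_hi"]) - float(cell["iqr_lo"])
        sigma = residual_scale * max(width / 1.349, 0.25)
        for r in range(n_readers):
            latent = float(cell["median"]) + biases[r]
            eps = rng.normal(0.0, sigma, size=n_patients) if sigma > 0 else np.zeros(n_patients)
            scores = np.clip(np.rint(latent + eps), 1, 5).astype(int)
            for p in range(n_patients):
                rows.append(
                    {
                        "reader": r + 1,
                        "patient": p + 1,
                        "kernel": cell["kernel"],
                        "qir": int(cell["qir"]),
                        "criterion": cell["criterion"],
                        "level": cell["level"],
                        "score": scores[p],
                    }
                )
    table = pd.DataFrame(rows)
    prov = {
        "generator": "synth_likert",
        "seed": seed,
        "n_patients": n_patients,
        "n_readers": n_readers,
        "residual_scale": residual_scale,
        "reader_bias_sd": reader_bias_sd,
    }
    return LikertDataset(table=table, provenance=prov)
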