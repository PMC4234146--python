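"""Tetrachoric correlations and first-principal-component wealth scores.

Binary asset indicators are modelled as dichotomized views of a latent
bivariate-normal "wealth" continuum. The tetrachoric correlation of two
indicators is the correlation of that latent normal, estimated by two-step
maximum likelihood: thresholds are fixed at the inverse-normal of the
margins, then rho maximizes the multinomial likelihood of the 2x2 table.
PCA on the tetrachoric correlation matrix (rather than on Pearson/phi
correlations of the raw 0/1 values) avoids the attenuation and spurious
factors that dichotomization induces; the first principal component is the
household wealth score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

RHO_CLAMP = 0.999
CONTINUITY_CORRECTION = 0.5


@dataclass
class TetrachoricMatrix:
    """Pairwise tetrachoric correlations with per-indicator thresholds."""

    rho: np.ndarray
    thresholds: np.ndarray
    indicator_names: list[str]
    psd_adjusted: bool = False
    boundary_pairs: list[tuple[str, str]] | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.indicator_names,
                            columns=self.indicator_names)


@dataclass
class PcaWealthIndex:
    """First-principal-component wealth score over a cohort."""

    loadings: dict[str, float]
    eigenvalue_share: float
    scores: np.ndarray
    household_ids: list[str]
    orientation_anchor: str


def _bivariate_upper_tail(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho."""
    if abs(rho) >= 1.0:
        rho = np.sign(rho) * (1 - 1e-12)
    cdf = stats.multivariate_normal.cdf(
        [h, k], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
        allow_singular=True,
    )
    # inclusion-exclusion: P(X>h, Y>k) = 1 - F(h) - F(k) + F2(h, k)
    return float(1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + cdf)


def table_log_likelihood(
    n11: float, n10: float, n01: float, n00: float, rho: float,
    h: float | None = None, k: float | None = None,
) -> float:
    """Multinomial log-likelihood of a 2x2 table under a thresholded
    bivariate normal with correlation ``rho``.

    Thresholds default to the inverse-normal of the observed margins.
    Exposed so an independent grid search can score the same likelihood.
    """
    total = n11 + n10 + n01 + n00
    p1 = (n11 + n10) / total  # P(first indicator = 1)
    p2 = (n11 + n01) / total
    if h is None:
        h = stats.norm.ppf(1 - p1)
    if k is None:
        k = stats.norm.ppf(1 - p2)
    p11 = _bivariate_upper_tail(h, k, rho)
    p10 = (1 - stats.norm.cdf(h)) - p11
    p01 = (1 - stats.norm.cdf(k)) - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.clip([p11, p10, p01, p00], 1e-12, 1.0)
    return float(np.dot([n11, n10, n01, n00], np.log(probs)))


def tetrachoric_from_table(
    n11: float, n10: float, n01: float, n00: float,
) -> tuple[float, bool]:
    """Two-step ML tetrachoric correlation of a 2x2 table.

    Returns ``(rho, boundary)``. Tables with an empty cell have no finite
    MLE (perfect association); they get a 0.5 continuity correction on all
    cells and the estimate is clamped to |rho| <= 0.999 with
    ``boundary=True``.
    """
    counts = np.array([n11, n10, n01, n00], dtype=float)
    if (counts < 0).any() or counts.sum() < 1:
        raise ValueError("cell counts must be non-negative with total >= 1")
    n11_, n10_, n01_, n00_ = counts
    if (n11_ + n10_ == 0) or (n01_ + n00_ == 0) or (n11_ + n01_ == 0) or (n10_ + n00_ == 0):
        raise ValueError("degenerate margin: a row or column of the table is empty")

    boundary = bool((counts == 0).any())
    if boundary:
        counts = counts + CONTINUITY_CORRECTION
    n11_, n10_, n01_, n00_ = counts

    result = optimize.minimize_scalar(
        lambda rho: -table_log_likelihood(n11_, n10_, n01_, n00_, rho),
        bounds=(-RHO_CLAMP, RHO_CLAMP),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(np.clip(result.x, -RHO_CLAMP, RHO_CLAMP))
    if abs(rho) >= RHO_CLAMP - 1e-4:
        boundary = True
        rho = float(np.sign(rho) * RHO_CLAMP)
    return rho, boundary


def nearest_psd(matrix: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-semidefinite correlation matrix.

    Negative eigenvalues are clipped to ``eps``, the matrix is rebuilt and
    its diagonal renormalized to 1 (so it remains a correlation matrix).
    """
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    clipped = np.clip(eigval, eps, None)
    rebuilt = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.clip(np.diag(rebuilt), 1e-12, None))
    rebuilt = rebuilt / np.outer(d, d)
    np.fill_diagonal(rebuilt, 1.0)
    return rebuilt


def tetrachoric_matrix(matrix, psd_tolerance: float = 1e-8) -> TetrachoricMatrix:
    """Pairwise tetrachoric correlation matrix of an IndicatorMatrix.

    Pairwise two-step ML estimates are not guaranteed to form a PSD matrix;
    if the smallest eigenvalue falls below ``-psd_tolerance`` the matrix is
    replaced by its nearest PSD correlation matrix and flagged.
    """
    values = matrix.values
    names = matrix.indicator_names
    p = len(names)
    rho = np.eye(p)
    boundary_pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            x, y = values[:, i], values[:, j]
            n11 = int(np.sum((x == 1) & (y == 1)))
            n10 = int(np.sum((x == 1) & (y == 0)))
            n01 = int(np.sum((x == 0) & (y == 1)))
            n00 = int(np.sum((x == 0) & (y == 0)))
            try:
                r, boundary = tetrachoric_from_table(n11, n10, n01, n00)
            except ValueError as err:
                raise ValueError(
                    f"tetrachoric estimation failed for pair "
                    f"({names[i]!r}, {names[j]!r}): {err}"
                ) from err
            rho[i, j] = rho[j, i] = r
            if boundary:
                boundary_pairs.append((names[i], names[j]))

    thresholds = stats.norm.ppf(1 - values.mean(axis=0))
    psd_adjusted = False
    if np.linalg.eigvalsh(rho).min() < -psd_tolerance:
        rho = nearest_psd(rho)
        psd_adjusted = True
    return TetrachoricMatrix(
        rho=rho, thresholds=thresholds, indicator_names=list(names),
        psd_adjusted=psd_adjusted, boundary_pairs=boundary_pairs,
    )


def pca_first_component(
    tetra: TetrachoricMatrix,
    matrix,
    orientation_anchor: str | None = None,
    multiplicity_tol: float = 1e-8,
) -> PcaWealthIndex:
    """First principal component of the tetrachoric matrix as a wealth score.

    Loadings are the leading eigenvector (unit norm). Each household's score
    is the loading-weighted sum of its standardized 0/1 indicators
    (centered at prevalence, scaled by the sample SD — the Filmer-Pritchett
    convention), then standardized to mean 0 / SD 1 over the cohort. The
    eigenvector's sign is fixed so the anchor indicator loads positively;
    the default anchor is the indicator most correlated with total asset
    ownership, so "more assets" scores higher.
    """
    eigval, eigvec = np.linalg.eigh(tetra.rho)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if len(eigval) > 1 and abs(eigval[0] - eigval[1]) <= multiplicity_tol:
        raise ValueError(
            "leading eigenvalue is (numerically) multiple; the first "
            "component is not identified — pass an explicit orientation_anchor "
            "and inspect the correlation matrix"
        )
    loadings = eigvec[:, 0]
    share = float(eigval[0] / eigval.sum())

    values = matrix.values.astype(float)
    prevalence = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        constant = [tetra.indicator_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant indicator column(s): {constant}")

    if orientation_anchor is None:
        total = values.sum(axis=1)
        corr = np.array([np.corrcoef(values[:, j], total)[0, 1]
                         for j in range(values.shape[1])])
        orientation_anchor = tetra.indicator_names[int(np.argmax(corr))]
    anchor_idx = tetra.indicator_names.index(orientation_anchor)
    if loadings[anchor_idx] < 0:
        loadings = -loadings

    standardized = (values - prevalence) / sd
    scores = standardized @ loadings
    scores = (scores - scores.mean()) / scores.std(ddof=1)

    return PcaWealthIndex(
        loadings=dict(zip(tetra.indicator_names, loadings.tolist())),
        eigenvalue_share=share,
        scores=scores,
        household_ids=list(matrix.household_ids),
        orientation_anchor=orientation_anchor,
    )
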