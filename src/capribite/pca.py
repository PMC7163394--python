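"""Principal component analysis of the goat-period trait means.

The eleven traits mix units (g DM/kg BW, ratios, per-min rates), so the PCA
is performed on the correlation matrix: each trait is centred and scaled to
unit variance before the eigendecomposition.  Loadings carry a
deterministic sign convention (the largest-magnitude loading of each
component is positive) so scores and plots are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repeatability import AnovaResult, fit_simplified_anova
from .traits import TRAIT_NAMES


@dataclass
class PcaResult:
    trait_order: list[str]
    loadings: pd.DataFrame  # traits x components
    scores: pd.DataFrame  # rows (goat-period) x components, with metadata
    explained_variance_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.explained_variance_pct)


def run_pca(mean_table: pd.DataFrame,
            traits: list[str] | None = None) -> PcaResult:
    """Correlation-matrix PCA of the goat-period means.

    Rows with any missing trait are dropped with a warning; a constant trait
    column is an error (it cannot be scaled to unit variance).
    """
    traits = traits or TRAIT_NAMES
    meta_cols = [c for c in ("goat_id", "breed", "period") if c in mean_table]
    df = mean_table[meta_cols + list(traits)].copy()
    complete = df[traits].notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} incomplete rows")
        df = df[complete]
    X = df[traits].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [t for t, s in zip(traits, sd) if s == 0]
        raise ValueError(f"constant trait column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    # sign convention: largest-magnitude loading per component positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=list(traits), columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, columns=comp_names, index=df.index)
    scores = pd.concat([df[meta_cols].reset_index(drop=True),
                        scores.reset_index(drop=True)], axis=1)
    explained = 100.0 * eigval / eigval.sum()
    return PcaResult(trait_order=list(traits), loadings=loadings,
                     scores=scores, explained_variance_pct=explained)


def score_anova(pca: PcaResult, components: tuple[str, ...] = ("PC1", "PC2"),
                ) -> dict[str, AnovaResult]:
    """Simplified-model ANOVA (breed on goat-within-breed; period and
    breed:period on residual) of the requested component scores."""
    out = {}
    for comp in components:
        out[comp] = fit_simplified_anova(pca.scores, comp)
    return out


def goat_barycentres(pca: PcaResult,
                     components: tuple[str, ...] = ("PC1", "PC2")) -> pd.DataFrame:
    """Per-goat mean of its period-level scores for the given components."""
    cols = [c for c in ("goat_id", "breed") if c in pca.scores]
    return (pca.scores.groupby(cols, sort=True)[list(components)]
            .mean().reset_index())
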