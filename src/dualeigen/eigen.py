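"""SVD of expression profiles with deterministic sign anchoring.

The log-scale profile E (genes x samples) is decomposed as
``E = sum_k rho_k * u_k * v_k^T`` with nonincreasing singular values rho_k,
gene eigenvectors u_k and sample eigenvectors v_k.  Two conventions used
throughout the package live here:

* the *contribution percentage* of the leading components is linear in the
  singular values, ``100 * sum_{k<=K} rho_k / sum_k rho_k`` (not in rho^2);
* the sign of each (u_k, v_k) pair is ambiguous, so it is anchored by the
  correlation of the sample loadings with a designated sample attribute
  (week of age, diet indicator, ...), which flips u_k and v_k together and
  leaves every product rho_k u_k v_k^T unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ExpressionProfile

CENTERING_MODES = ("none", "gene", "sample", "double")

ORTHONORMALITY_TOL = 1e-8
RECONSTRUCTION_TOL = 1e-6


@dataclass
class EigenDecomposition:
    """Ordered eigen-components (rho_k, u_k, v_k) of one expression profile."""

    rho: np.ndarray                 # (k,) nonincreasing, nonnegative
    u: np.ndarray                   # (g, k) gene eigenvectors, orthonormal columns
    v: np.ndarray                   # (s, k) sample eigenvectors, orthonormal columns
    genes: pd.Index
    samples: pd.Index
    centering: str = "gene"
    anchors: dict = field(default_factory=dict)   # component index -> anchor record

    @property
    def n_components(self) -> int:
        return len(self.rho)

    def gene_loadings(self, k: int) -> pd.Series:
        return pd.Series(self.u[:, k], index=self.genes, name=f"u{k + 1}")

    def sample_loadings(self, k: int) -> pd.Series:
        return pd.Series(self.v[:, k], index=self.samples, name=f"v{k + 1}")

    def reconstruct(self) -> np.ndarray:
        return (self.u * self.rho) @ self.v.T


def center_matrix(m: np.ndarray, centering: str) -> np.ndarray:
    if centering not in CENTERING_MODES:
        raise ValueError(f"unknown centering mode {centering!r}")
    if centering == "none":
        return m
    out = m.astype(float, copy=True)
    if centering in ("gene", "double"):
        out -= out.mean(axis=1, keepdims=True)
    if centering in ("sample", "double"):
        out -= out.mean(axis=0, keepdims=True)
    return out


def compute_svd(profile: ExpressionProfile, centering: str = "gene") -> EigenDecomposition:
    """Full SVD of the (centered) expression matrix.

    Components are sorted by singular value, descending; LAPACK's
    deterministic Golub-Kahan path is used (no randomized initialization),
    so repeated calls on the same input agree bitwise.  Zero-variance genes
    under gene-centering simply contribute zero rows; they are kept.
    """
    m = center_matrix(profile.matrix(), centering)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    return EigenDecomposition(
        rho=s,
        u=u,
        v=vt.T,
        genes=profile.genes,
        samples=profile.samples,
        centering=centering,
    )


def contribution_percentages(rho: np.ndarray) -> np.ndarray:
    """Cumulative contribution (percent) of the leading singular values.

    The convention is linear in rho: the cumulative percentage at rank K is
    ``100 * sum_{k<=K} rho_k / sum_k rho_k``.  Scale-invariant by design.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 1 or len(rho) == 0:
        raise ValueError("rho must be a nonempty 1-D sequence")
    if (rho < -1e-12).any():
        raise ValueError("singular values must be nonnegative")
    if (np.diff(rho) > 1e-9 * max(1.0, rho[0])).any():
        raise ValueError("singular values must be nonincreasing")
    total = rho.sum()
    if total <= 0:
        raise ValueError("all singular values are zero")
    return 100.0 * np.cumsum(rho) / total


def _encode_anchor(values: pd.Series) -> np.ndarray:
    """Numeric encoding of an anchor attribute (diet -> HFD indicator, etc.)."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        uniq = sorted(set(values.dropna()))
        if uniq == ["HFD", "RC"]:
            return (values == "HFD").astype(float).to_numpy()
        mapping = {level: i for i, level in enumerate(uniq)}
        return values.map(mapping).astype(float).to_numpy()
    return values.astype(float).to_numpy()


def fix_signs(
    decomposition: EigenDecomposition,
    attributes: pd.DataFrame,
    anchor: str | dict = "week",
) -> EigenDecomposition:
    """Resolve the per-component sign ambiguity against a sample attribute.

    Each v_k (with its u_k) is flipped so that the Spearman correlation of
    the sample loadings with the anchor attribute is nonnegative.  A
    component with exactly zero (or undefined) correlation is anchored by
    making its largest-magnitude sample loading positive, and flagged.
    """
    if isinstance(anchor, str):
        anchor_by_k = {k: anchor for k in range(decomposition.n_components)}
    else:
        anchor_by_k = dict(anchor)

    u = decomposition.u.copy()
    v = decomposition.v.copy()
    records: dict = {}
    attributes = attributes.loc[decomposition.samples]
    for k, attr_name in anchor_by_k.items():
        if attr_name not in attributes.columns:
            raise KeyError(f"anchor attribute {attr_name!r} not present")
        col = attributes[attr_name]
        mask = col.notna().to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"anchor {attr_name!r} present for < 2 samples")
        x = _encode_anchor(col[mask])
        load = v[mask, k]
        import warnings

        with warnings.catch_warnings():
            # a constant anchor/loading is handled explicitly below
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            corr = stats.spearmanr(load, x).statistic
        degenerate = not np.isfinite(corr) or corr == 0.0
        if degenerate:
            flip = load[np.argmax(np.abs(load))] < 0
        else:
            flip = corr < 0
        if flip:
            u[:, k] *= -1.0
            v[:, k] *= -1.0
        records[k] = {
            "attribute": attr_name,
            "spearman": float(corr) if np.isfinite(corr) else float("nan"),
            "flipped": bool(flip),
            "degenerate": bool(degenerate),
        }
    return replace(decomposition, u=u, v=v, anchors=records)
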