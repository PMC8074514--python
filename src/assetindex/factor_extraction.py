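"""Extraction backends for the asset index: PCA, one-factor minres EFA, MCA.

The benchmark index is the first principal component of the pooled
correlation matrix.  Loadings are reported on the "standardized" scale
(eigenvector entries × √λ₁ — the correlation of each item with the
component); the unit-norm eigenvector is kept as the scoring vector, so
scores have mean 0 and SD √λ₁ on the fitting sample.

EFA extracts a single factor by minimizing the squared off-diagonal residuals
of the correlation matrix (minres); with one factor, varimax rotation is the
identity.  Factor scores use the regression method z·R⁻¹·l.

MCA runs correspondence analysis on the complete disjunctive coding of binary
items (two indicator columns per item); household scores are first-dimension
row principal coordinates, and item loadings are reported as the column
principal coordinates of the "owned"/level-1 categories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .correlation_engines import CorrelationMatrix

__all__ = [
    "IndexModel",
    "fit_pca",
    "fit_efa_minres",
    "fit_mca",
    "score",
    "orient",
    "DEFAULT_REFERENCE_ITEM",
]

DEFAULT_REFERENCE_ITEM = "electricity"


@dataclass
class IndexModel:
    """A fitted one-dimensional index: loadings, scale and scoring parameters.

    ``weights`` is what scoring applies to standardized columns (unit-norm
    eigenvector for PCA, R⁻¹l for EFA); ``loadings`` is the reported
    per-item loading.  For MCA the scoring machinery lives in ``mca_params``.
    """

    method: str  # pca | efa | mca
    corr_kind: str
    items: list[str]
    loadings: np.ndarray
    weights: np.ndarray | None
    variance_explained: float
    eigenvalue: float | None
    means: pd.Series | None = None
    sds: pd.Series | None = None
    reference: str = DEFAULT_REFERENCE_ITEM
    mca_params: dict | None = None
    flags: list[str] = field(default_factory=list)

    def loading(self, item: str) -> float:
        return float(self.loadings[self.items.index(item)])

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "corr_kind": self.corr_kind,
            "items": self.items,
            "loadings": list(map(float, self.loadings)),
            "weights": list(map(float, self.weights)) if self.weights is not None else None,
            "variance_explained": self.variance_explained,
            "eigenvalue": self.eigenvalue,
            "means": self.means.to_dict() if self.means is not None else None,
            "sds": self.sds.to_dict() if self.sds is not None else None,
            "reference": self.reference,
            "mca_params": (
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.mca_params.items()}
                if self.mca_params
                else None
            ),
            "flags": self.flags,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "IndexModel":
        d = json.loads(Path(path).read_text())
        mca = d.get("mca_params")
        if mca:
            mca = {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in mca.items()}
        return cls(
            method=d["method"],
            corr_kind=d["corr_kind"],
            items=list(d["items"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float) if d.get("weights") is not None else None,
            variance_explained=float(d["variance_explained"]),
            eigenvalue=d.get("eigenvalue"),
            means=pd.Series(d["means"]) if d.get("means") else None,
            sds=pd.Series(d["sds"]) if d.get("sds") else None,
            reference=d.get("reference", DEFAULT_REFERENCE_ITEM),
            mca_params=mca,
            flags=list(d.get("flags") or ()),
        )


def _attach_scaling(model: IndexModel, design) -> IndexModel:
    if design is not None:
        model.means = design.means.copy()
        model.sds = design.sds.copy()
    return model


def fit_pca(
    corr: CorrelationMatrix,
    design=None,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> IndexModel:
    """First principal component of a correlation matrix.

    variance_explained = λ₁/p; loadings = eigenvector × √λ₁; the unit-norm
    eigenvector is the scoring vector.  Pass the fitted PooledDesign to store
    the pooled means/SDs needed for out-of-sample scoring.
    """
    m = corr.matrix
    w, v = np.linalg.eigh(m)
    lam1 = float(w[-1])
    vec = v[:, -1]
    if lam1 <= 0:
        raise ValueError("leading eigenvalue not positive; smooth the matrix upstream")
    model = IndexModel(
        method="pca",
        corr_kind=corr.kind,
        items=list(corr.items),
        loadings=vec * np.sqrt(lam1),
        weights=vec.copy(),
        variance_explained=lam1 / corr.p,
        eigenvalue=lam1,
        reference=reference,
    )
    return orient(_attach_scaling(model, design))


def fit_efa_minres(
    corr: CorrelationMatrix,
    design=None,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> IndexModel:
    """One-factor minres EFA: minimize Σ_{i<j} (r_ij − l_i l_j)².

    Varimax with a single factor is the identity, so no rotation step exists.
    A Heywood solution (l_i² > 1) is clipped to communality 0.995 and flagged.
    Scoring uses regression-method weights computed under the fitted model,
    (llᵀ + Ψ)⁻¹l with Ψ = diag(1 − l²): algebraically the usual z·Σ⁻¹l, but
    stable when the sample matrix is near-singular (e.g. a smoothed
    polychoric matrix, whose floored eigenvalues would otherwise amplify
    noise catastrophically in R⁻¹).
    """
    r = corr.matrix
    p = corr.p
    mask = ~np.eye(p, dtype=bool)

    def objective(l: np.ndarray) -> float:
        resid = (r - np.outer(l, l))[mask]
        return 0.5 * float(resid @ resid)

    def grad(l: np.ndarray) -> np.ndarray:
        resid = np.where(mask, r - np.outer(l, l), 0.0)
        return -2.0 * resid @ l

    # start from the PCA loadings
    w, v = np.linalg.eigh(r)
    l0 = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
    res = optimize.minimize(objective, l0, jac=grad, method="L-BFGS-B")
    l = res.x
    flags = []
    if np.any(l**2 > 1.0):
        l = np.clip(l, -np.sqrt(0.995), np.sqrt(0.995))
        flags.append("heywood_clipped")
        warnings.warn("Heywood case: communality clipped to 0.995", stacklevel=2)
    psi = np.clip(1.0 - l**2, 0.005, None)
    weights = np.linalg.solve(np.outer(l, l) + np.diag(psi), l)
    model = IndexModel(
        method="efa",
        corr_kind=corr.kind,
        items=list(corr.items),
        loadings=l,
        weights=weights,
        variance_explained=float(np.sum(l**2)) / p,
        eigenvalue=None,
        reference=reference,
        flags=flags,
    )
    return orient(_attach_scaling(model, design))


def _disjunctive(values: pd.DataFrame) -> np.ndarray:
    """Complete disjunctive coding: columns (item=0, item=1) per binary item."""
    x = values.to_numpy(dtype=float)
    n, p = x.shape
    g = np.empty((n, 2 * p))
    g[:, 0::2] = 1.0 - x
    g[:, 1::2] = x
    return g


def fit_mca(
    values: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE_ITEM,
) -> IndexModel:
    """Multiple correspondence analysis of binary items, first dimension.

    Correspondence analysis of the indicator matrix: with correspondence
    matrix P = G/g.., row masses r and column masses c, the standardized
    residuals S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} are decomposed by SVD.
    Household scores are first-dimension row principal coordinates; reported
    item loadings are the column principal coordinates of the level-1
    categories.  Constant items are dropped with a warning.
    """
    values = pd.DataFrame(values)
    keep = [c for c in values.columns if values[c].nunique() > 1]
    dropped = [c for c in values.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant items from MCA: {dropped}", stacklevel=2)
    values = values[keep]
    if values.shape[1] < 2:
        raise ValueError("MCA needs at least 2 varying items")
    bad = ~values.isin([0, 1]).all()
    if bad.any():
        raise ValueError(f"MCA requires binary items; offending: {list(values.columns[bad])}")

    g = _disjunctive(values)
    total = g.sum()
    p_mat = g / total
    r = p_mat.sum(axis=1)
    c = p_mat.sum(axis=0)
    s = (p_mat - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    # first non-trivial dimension (indicator CA has no trivial unit sv)
    sigma1 = float(sv[0])
    b_std = vt[0] / np.sqrt(c)  # column standard coordinates
    inertia = float(np.sum(sv**2))
    model = IndexModel(
        method="mca",
        corr_kind="none",
        items=list(values.columns),
        loadings=(b_std * sigma1)[1::2],  # level-1 column principal coordinates
        weights=None,
        variance_explained=sigma1**2 / inertia if inertia > 0 else 0.0,
        eigenvalue=sigma1**2,
        reference=reference,
        mca_params={
            "col_standard": b_std,
            "col_masses": c,
            "sigma1": sigma1,
            "n_items": values.shape[1],
        },
    )
    return orient(model)


def _mca_scores(model: IndexModel, values: pd.DataFrame) -> np.ndarray:
    """Row principal coordinates from the transition formula.

    f_i = Σ_j (p_ij/r_i)·b_j − Σ_j c_j·b_j with b the column standard
    coordinates, then scaled by σ₁ to principal coordinates... the σ scaling
    is already folded in: f = (row profile)·b − c·b gives principal
    coordinates directly because b are standard coordinates of the SVD of S.
    """
    q = model.mca_params["n_items"]
    b = np.asarray(model.mca_params["col_standard"], dtype=float)
    c = np.asarray(model.mca_params["col_masses"], dtype=float)
    g = _disjunctive(values[model.items])
    profile = g / q  # each row of G sums to the number of items
    return profile @ b - float(c @ b)


def score(model: IndexModel, design) -> pd.Series:
    """Index scores for a design, using the model's stored scaling.

    For PCA/EFA the design columns are standardized with the model's pooled
    means/SDs, then projected on the scoring weights.  For MCA pass raw
    binary values (PooledDesign.raw or a DataFrame).
    """
    raw = design.raw if hasattr(design, "raw") else pd.DataFrame(design)
    missing = [c for c in model.items if c not in raw.columns]
    if missing:
        raise ValueError(f"design lacks model items: {missing}")
    x = raw[model.items]
    if model.method == "mca":
        vals = _mca_scores(model, x)
    else:
        if model.means is None or model.sds is None:
            raise ValueError("model has no stored scaling; fit with a design attached")
        z = (x - model.means[model.items]) / model.sds[model.items]
        vals = z.to_numpy() @ model.weights
    return pd.Series(vals, index=x.index, name="score")


def orient(model: IndexModel, reference: str | None = None) -> IndexModel:
    """Fix the sign so the reference item loads non-negatively (idempotent).

    If the reference item is absent or loads exactly 0, the majority-positive
    rule applies.  Orientation never forces *all* loadings positive — an item
    whose relevance reverses over time may legitimately load negative.
    """
    ref = reference or model.reference
    flip = False
    if ref in model.items and model.loading(ref) != 0.0:
        flip = model.loading(ref) < 0
    else:
        flip = np.sum(model.loadings > 0) < np.sum(model.loadings < 0)
    if flip:
        model.loadings = -model.loadings
        if model.weights is not None:
            model.weights = -model.weights
        if model.mca_params is not None:
            model.mca_params["col_standard"] = -np.asarray(model.mca_params["col_standard"])
    model.reference = ref
    return model
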