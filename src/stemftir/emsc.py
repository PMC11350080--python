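"""Extended multiplicative signal correction with chemical components.

Each measured spectrum ``s`` is modelled as

    s = a * m_bar + sum_i d_i * P_i(x) + sum_j c_j * K_j + e

where ``m_bar`` is a reference spectrum (by default the mean of the
batch under analysis), ``P_i`` are Legendre polynomials of the
wavenumber rescaled to [-1, 1] (multiplicative-scatter baseline terms),
``K_j`` are unit-norm reference component spectra (holocellulose
monomer signatures, lignin variants, pectin, proteins, ...), ``a`` is
the multiplicative scatter scale and ``e`` the residual. Solving the
linear system per spectrum yields simultaneous scatter correction and
component quantification.

Because ``m_bar`` itself carries chemistry, the raw component
coefficients ``c_j`` are deviations from the reference composition. The
identifiable chemistry-only loadings are ``t_j = c_j + a * u_j`` where
``u_j`` is the loading of component ``j`` in ``m_bar`` (computed once at
model build). Relative absorbance of a component is ``|t_j| / sum |t|``
— the compound's absorbance in relation to the total fitted chemical
absorbance — and is invariant to rescaling of the input spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import optimize

from .io_spectra import HyperCube, SpectrumTable, WavenumberAxis

__all__ = [
    "ComponentLibrary",
    "EMSCModel",
    "EMSCFit",
    "CubeFit",
    "build_model",
    "fit_spectrum",
    "fit_table",
    "fit_cube",
    "correct_spectrum",
    "pca_scores",
]

CATEGORIES = (
    "hemicellulose_monomer",
    "cellulose",
    "lignin",
    "pectin",
    "protein",
    "lipid",
    "paraffin",
    "other",
)


@dataclass
class ComponentLibrary:
    """Named reference component spectra on a shared axis, unit L2 norm."""

    axis: WavenumberAxis
    names: list[str]
    categories: list[str]
    spectra: np.ndarray  # (n_components, n_channels)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != len(self.axis):
            raise ValueError("library spectra must be (n_components, axis length)")
        if len(self.names) != self.spectra.shape[0]:
            raise ValueError("names length != number of spectra")
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        if len(self.categories) != len(self.names):
            raise ValueError("categories length != names length")
        for cat in self.categories:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
        if np.any(self.spectra < 0):
            raise ValueError("component spectra must be nonnegative")
        norms = np.linalg.norm(self.spectra, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm component spectrum")
        # idempotent: leave rows that are already unit norm untouched so
        # that construction from round-tripped data is exact
        off = np.abs(norms - 1.0) > 1e-12
        if off.any():
            self.spectra = self.spectra.copy()
            self.spectra[off] /= norms[off, None]

    @property
    def n_components(self) -> int:
        return len(self.names)

    def truncate(self, lo: float, hi: float) -> "ComponentLibrary":
        keep = self.axis.slice_mask(lo, hi)
        return ComponentLibrary(
            WavenumberAxis(self.axis.values[keep]),
            list(self.names),
            list(self.categories),
            self.spectra[:, keep].copy(),
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            self.spectra, columns=[repr(float(v)) for v in self.axis.values]
        )
        df.insert(0, "category", self.categories)
        df.insert(0, "name", self.names)
        df.to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentLibrary":
        df = pd.read_csv(path, float_precision="round_trip")
        wn_cols = [c for c in df.columns if c not in ("name", "category")]
        wns = np.array([float(c) for c in wn_cols])
        order = np.argsort(wns)[::-1]
        return cls(
            WavenumberAxis(wns[order]),
            df["name"].astype(str).tolist(),
            df["category"].astype(str).tolist(),
            df[wn_cols].to_numpy(dtype=float)[:, order],
        )


def _legendre_terms(axis: WavenumberAxis, poly_order: int) -> np.ndarray:
    """Columns P_0..P_p of Legendre polynomials on the rescaled axis."""
    v = axis.values
    x = 2.0 * (v - v.min()) / (v.max() - v.min()) - 1.0
    cols = []
    for i in range(poly_order + 1):
        coef = np.zeros(i + 1)
        coef[i] = 1.0
        cols.append(legendre.legval(x, coef))
    return np.column_stack(cols)


@dataclass
class EMSCModel:
    axis: WavenumberAxis
    m_bar: np.ndarray
    poly_order: int
    library: ComponentLibrary
    design: np.ndarray  # channels x (2 + p + J)
    ref_loadings: np.ndarray  # component loadings of m_bar, shape (J,)
    condition_number: float
    _pinv: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.library.n_components

    def coefficient_slices(self) -> tuple[slice, slice, slice]:
        p = self.poly_order
        return slice(0, 1), slice(1, p + 2), slice(p + 2, p + 2 + self.n_components)


def build_model(
    reference_set: SpectrumTable | np.ndarray,
    library: ComponentLibrary,
    poly_order: int = 2,
) -> EMSCModel:
    """Assemble the EMSC design matrix [m_bar | P_0..P_p | K_1..K_J].

    ``m_bar`` is the channel-wise mean of the reference set. Collinear
    library/baseline columns raise; a reference spectrum lying (nearly)
    in their span only degrades the condition number, which is reported
    and warned about above 1e8 — the least-squares fit then uses the
    minimum-norm solution, and the chemical loadings remain well defined.
    """
    if isinstance(reference_set, SpectrumTable):
        if reference_set.axis != library.axis:
            raise ValueError("reference set axis != library axis")
        spectra = reference_set.absorbance
    else:
        spectra = np.atleast_2d(np.asarray(reference_set, dtype=float))
        if spectra.shape[1] != len(library.axis):
            raise ValueError("reference spectra length != library axis length")
    if spectra.shape[0] == 0:
        raise ValueError("empty reference set")
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")

    m_bar = spectra.mean(axis=0)
    P = _legendre_terms(library.axis, poly_order)
    K = library.spectra.T  # channels x J
    base = np.column_stack([P, K])
    # Rank of the baseline+component block: duplicates here are user error.
    rank = np.linalg.matrix_rank(base, tol=None)
    if rank < base.shape[1]:
        raise ValueError(
            "rank-deficient design: collinear component/baseline spectra in library"
        )
    design = np.column_stack([m_bar, base])
    cond = float(np.linalg.cond(design))
    if cond > 1e8:
        warnings.warn(
            f"EMSC design condition number {cond:.3g} > 1e8; reference spectrum "
            "is (nearly) collinear with baseline+component span",
            RuntimeWarning,
            stacklevel=2,
        )
    # Loadings of m_bar on the baseline+component block (unique: base full rank).
    theta_ref, *_ = np.linalg.lstsq(base, m_bar, rcond=None)
    ref_loadings = theta_ref[poly_order + 1 :]
    pinv = np.linalg.pinv(design)
    return EMSCModel(
        axis=library.axis,
        m_bar=m_bar,
        poly_order=poly_order,
        library=library,
        design=design,
        ref_loadings=ref_loadings,
        condition_number=cond,
        _pinv=pinv,
    )


@dataclass
class EMSCFit:
    """Per-spectrum decomposition: scale, baseline, component loadings."""

    a: float
    baseline: np.ndarray  # d_0..d_p
    components: np.ndarray  # raw c_1..c_J (deviations from a*m_bar)
    chemical_loadings: np.ndarray  # t_j = c_j + a * u_j
    relative_absorbance: dict[str, float]
    residual_rms: float
    degenerate: bool  # a <= 0


def _relative_absorbance(
    names: list[str], loadings: np.ndarray
) -> dict[str, float]:
    mags = np.abs(loadings)
    total = mags.sum()
    if total == 0:
        return {n: 0.0 for n in names}
    return dict(zip(names, (mags / total).tolist()))


def _fit_from_theta(model: EMSCModel, s: np.ndarray, theta: np.ndarray) -> EMSCFit:
    sl_a, sl_d, sl_c = model.coefficient_slices()
    a = float(theta[sl_a][0])
    d = theta[sl_d].copy()
    c = theta[sl_c].copy()
    t = c + a * model.ref_loadings
    resid = s - model.design @ theta
    degenerate = a <= 0
    if degenerate:
        warnings.warn(
            f"degenerate EMSC fit: multiplicative scale a={a:.4g} <= 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return EMSCFit(
        a=a,
        baseline=d,
        components=c,
        chemical_loadings=t,
        relative_absorbance=_relative_absorbance(model.library.names, t),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        degenerate=degenerate,
    )


def _pls_nipals(X: np.ndarray, y: np.ndarray, n_latent: int) -> np.ndarray:
    """PLS1 regression coefficients via NIPALS (no centering).

    With n_latent equal to the column rank of X this reproduces the
    least-squares solution; fewer latent variables trade bias for noise
    robustness.
    """
    Xk = X.copy()
    yk = y.astype(float).copy()
    W, Ps, qs = [], [], []
    for _ in range(n_latent):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xk @ w
        tt = t @ t
        if tt < 1e-28:
            break
        p = Xk.T @ t / tt
        q = yk @ t / tt
        Xk = Xk - np.outer(t, p)
        yk = yk - q * t
        W.append(w)
        Ps.append(p)
        qs.append(q)
    if not W:
        return np.zeros(X.shape[1])
    W = np.column_stack(W)
    P = np.column_stack(Ps)
    q = np.array(qs)
    return W @ np.linalg.solve(P.T @ W, q)


def fit_spectrum(
    model: EMSCModel,
    s: np.ndarray,
    solver: str = "ols",
    n_latent: int | None = None,
) -> EMSCFit:
    """Decompose one spectrum against the model design.

    solver: ``ols`` (default, minimum-norm least squares),
    ``nnls_components`` (component coefficients constrained >= 0),
    ``pls`` (NIPALS with ``n_latent`` latent variables, default full rank).
    """
    s = np.asarray(s, dtype=float).ravel()
    if s.size != len(model.axis):
        raise ValueError("spectrum length != model axis length")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite values in spectrum")

    if solver == "ols":
        theta = model._pinv @ s
    elif solver == "nnls_components":
        ncols = model.design.shape[1]
        _, _, sl_c = model.coefficient_slices()
        lb = np.full(ncols, -np.inf)
        lb[sl_c] = 0.0
        res = optimize.lsq_linear(model.design, s, bounds=(lb, np.full(ncols, np.inf)))
        theta = res.x
    elif solver == "pls":
        k = n_latent if n_latent is not None else model.design.shape[1]
        theta = _pls_nipals(model.design, s, k)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return _fit_from_theta(model, s, theta)


def fit_table(
    model: EMSCModel, table: SpectrumTable, solver: str = "ols"
) -> list[EMSCFit]:
    return [fit_spectrum(model, s, solver=solver) for s in table.absorbance]


def correct_spectrum(model: EMSCModel, fit: EMSCFit, s: np.ndarray) -> np.ndarray:
    """Scatter/baseline-corrected spectrum: (s - baseline) / a."""
    if fit.a == 0:
        raise ZeroDivisionError("degenerate fit: a = 0")
    _, sl_d, _ = model.coefficient_slices()
    baseline = model.design[:, sl_d] @ fit.baseline
    return (np.asarray(s, dtype=float) - baseline) / fit.a


@dataclass
class CubeFit:
    """Per-pixel EMSC results on a cube; masked pixels hold NaN."""

    names: list[str]
    relative_absorbance: np.ndarray  # rows x cols x J, NaN off-mask
    chemical_loadings: np.ndarray  # rows x cols x J
    scale: np.ndarray  # rows x cols (a)
    residual_rms: np.ndarray  # rows x cols
    mask: np.ndarray
    n_degenerate: int

    def component_map(self, name: str) -> np.ndarray:
        return self.relative_absorbance[:, :, self.names.index(name)]

    def valid_mask(self) -> np.ndarray:
        """Pixels usable for statistics: unmasked and non-degenerate."""
        return self.mask & (self.scale > 0)


def fit_cube(model: EMSCModel, cube: HyperCube, solver: str = "ols") -> CubeFit:
    """Vectorized EMSC decomposition of every unmasked pixel.

    OLS solves all pixels in one matrix product; other solvers loop.
    Degenerate pixels (a <= 0) are counted and excluded by
    :meth:`CubeFit.valid_mask`, never imputed.
    """
    if cube.axis != model.axis:
        raise ValueError("cube axis != model axis")
    rows, cols, m = cube.shape
    J = model.n_components
    rel = np.full((rows, cols, J), np.nan)
    load = np.full((rows, cols, J), np.nan)
    scale = np.full((rows, cols), np.nan)
    rms = np.full((rows, cols), np.nan)
    if not cube.mask.any():
        warnings.warn("fully masked cube: empty component maps", RuntimeWarning)
        return CubeFit([*model.library.names], rel, load, scale, rms, cube.mask.copy(), 0)

    S = cube.data[cube.mask]  # n_pixels x channels
    if solver == "ols":
        theta = S @ model._pinv.T  # n_pixels x n_coef
    else:
        theta = np.array(
            [
                np.concatenate(
                    (
                        [f.a],
                        f.baseline,
                        f.components,
                    )
                )
                for f in (fit_spectrum(model, s, solver=solver) for s in S)
            ]
        )
    sl_a, _, sl_c = model.coefficient_slices()
    a = theta[:, sl_a].ravel()
    c = theta[:, sl_c]
    t = c + a[:, None] * model.ref_loadings[None, :]
    mags = np.abs(t)
    totals = mags.sum(axis=1)
    frac = np.divide(
        mags, totals[:, None], out=np.zeros_like(mags), where=totals[:, None] > 0
    )
    resid = S - theta @ model.design.T
    n_degenerate = int(np.sum(a <= 0))

    rel[cube.mask] = frac
    load[cube.mask] = t
    scale[cube.mask] = a
    rms[cube.mask] = np.sqrt(np.mean(resid**2, axis=1))
    return CubeFit(
        names=[*model.library.names],
        relative_absorbance=rel,
        chemical_loadings=load,
        scale=scale,
        residual_rms=rms,
        mask=cube.mask.copy(),
        n_degenerate=n_degenerate,
    )


def pca_scores(
    table: SpectrumTable, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centred PCA of the spectra.

    Returns (scores, loadings, explained variance fractions). Sign
    convention: the largest-magnitude element of each loading vector is
    positive.
    """
    from sklearn.decomposition import PCA

    X = table.absorbance
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} > max rank {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return scores, loadings, pca.explained_variance_ratio_
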