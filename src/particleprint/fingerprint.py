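"""Population "fingerprints": bivariate Gaussian KDEs of 2D embeddings.

A fingerprint is the kernel density estimate of a particle population's 2D
embedding scatter, using a Gaussian kernel with a full (unconstrained,
off-diagonals included) 2x2 bandwidth matrix chosen by a two-stage plug-in
selector.  The module also supplies the utilities used to read a
fingerprint: highest-density-region (HDR) contour levels, the global pdf
mode, and nearest-embedding curation (the ~50 images closest to the mode
give a representative gallery of the population's morphology).

Plug-in bandwidth selector
--------------------------
The asymptotic MISE of a bivariate Gaussian KDE with bandwidth matrix H is

    AMISE(H) = (4 pi)^(-1) n^(-1) |H|^(-1/2) + (1/4) * Q_psi(H),

where ``Q_psi`` is a quadratic form in the entries of H whose coefficients
are the integrated fourth-order density derivative functionals
``psi_r = int D^r f(x) f(x) dx``, |r| = 4.  The selector:

1. pre-spheres the data with the symmetric square root of the sample
   covariance (making the final estimate exactly scale- and
   rotation-equivariant);
2. computes a common isotropic pilot bandwidth g by minimizing the summed
   squared asymptotic bias of the five psi-hat estimators under a normal
   reference (whose sixth-order functionals are closed-form);
3. estimates the five fourth-order functionals with the leave-none-out
   double sum ``psi_hat_r = n^-2 sum_ij D^r phi_{g^2 I}(X_i - X_j)``;
4. minimizes the plug-in AMISE over SPD matrices (Cholesky parametrization,
   BFGS with analytic gradient, Newton polish), and back-transforms.

For data that are truly bivariate normal the AMISE-optimal bandwidth is
``n^(-1/3) * Sigma`` at d = 2, which serves as the closed-form oracle for
this implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

from .nn import EmbeddingSet

__all__ = [
    "Fingerprint",
    "HDRLevelSet",
    "ModeResult",
    "plugin_bandwidth",
    "fit_fingerprint",
    "kde_pdf",
    "hdr_levels",
    "hdr_mass",
    "global_mode",
    "nearest_to_point",
    "normal_reference_bandwidth",
]

MIN_POINTS = 8


# ---------------------------------------------------------------------------
# Gaussian derivative helpers
# ---------------------------------------------------------------------------

def _hermite_prob(k: int, t: np.ndarray):
    """Probabilists' Hermite polynomial He_k, k <= 6."""
    if k == 0:
        return np.ones_like(t)
    if k == 1:
        return t
    if k == 2:
        return t * t - 1.0
    if k == 3:
        return t ** 3 - 3.0 * t
    if k == 4:
        return t ** 4 - 6.0 * t * t + 3.0
    if k == 5:
        return t ** 5 - 10.0 * t ** 3 + 15.0 * t
    if k == 6:
        return t ** 6 - 15.0 * t ** 4 + 45.0 * t * t - 15.0
    raise ValueError(k)


def _phi_deriv0(k: int, sigma2: float) -> float:
    """k-th derivative of a 1D N(0, sigma2) pdf at 0 (0 for odd k)."""
    if k % 2 == 1:
        return 0.0
    sig = np.sqrt(sigma2)
    # phi_sigma^{(k)}(0) = sigma^{-k} (-1)^k He_k(0) phi_sigma(0); He_k(0) for
    # even k is (-1)^{k/2} (k-1)!!
    dfact = 1.0
    for j in range(k - 1, 0, -2):
        dfact *= j
    he0 = ((-1) ** (k // 2)) * dfact
    return he0 / sig ** k / (sig * np.sqrt(2.0 * np.pi))


def _psi_normal_ref(r: tuple[int, int], Sigma_diag: float = 1.0) -> float:
    """psi_r for a bivariate normal with covariance Sigma_diag * I.

    psi_r = D^r (f * f)(0) = D^r phi_{2 Sigma}(0), separable across axes.
    """
    s2 = 2.0 * Sigma_diag
    return _phi_deriv0(r[0], s2) * _phi_deriv0(r[1], s2)


_R4 = [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]


def _pilot_bandwidth(n: int) -> float:
    """Common isotropic pilot g for the psi4 functionals (sphered data).

    Minimizes the summed squared asymptotic bias of the five estimators
    under a standard-normal reference: for each r the bias is
    ``n^-1 g^-6 D^r phi(0) + (g^2 / 2) sum_j psi_{r+2e_j}``.  A single,
    data-independent pilot keeps the whole selector exactly
    rotation-equivariant after sphering.
    """
    A = np.array([_phi_deriv0(r1, 1.0) * _phi_deriv0(r2, 1.0) for r1, r2 in _R4])
    B = np.array([
        _psi_normal_ref((r1 + 2, r2)) + _psi_normal_ref((r1, r2 + 2))
        for r1, r2 in _R4
    ])

    def sq_bias(log_g: float) -> float:
        g = np.exp(log_g)
        bias = A / (n * g ** 6) + 0.5 * g * g * B
        return float((bias * bias).sum())

    res = optimize.minimize_scalar(sq_bias, bounds=(np.log(1e-3), np.log(10.0)),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    return float(np.exp(res.x))


def _psi4_hat(z: np.ndarray, g: float) -> dict[tuple[int, int], float]:
    """Double-sum estimates of the five fourth-order functionals.

    psi_hat_r = n^-2 sum_{i,j} D^r phi_{g^2 I}(z_i - z_j), diagonal terms
    included (their bias is what the pilot g is tuned to cancel).
    Chunked over pairs; O(n^2) time, O(chunk^2) memory.
    """
    n = len(z)
    acc = {r: 0.0 for r in _R4}
    chunk = 2048
    inv_g = 1.0 / g
    norm = inv_g ** 6 / (2.0 * np.pi)  # g^-(d + |r|) * phi normalization
    for i0 in range(0, n, chunk):
        zi = z[i0:i0 + chunk]
        for j0 in range(i0, n, chunk):
            zj = z[j0:j0 + chunk]
            t1 = (zi[:, None, 0] - zj[None, :, 0]) * inv_g
            t2 = (zi[:, None, 1] - zj[None, :, 1]) * inv_g
            s1, s2 = t1 * t1, t2 * t2
            w = np.exp(-0.5 * (s1 + s2))
            he2_1, he2_2 = s1 - 1.0, s2 - 1.0
            he3_1, he3_2 = t1 * (s1 - 3.0), t2 * (s2 - 3.0)
            he4_1, he4_2 = s1 * (s1 - 6.0) + 3.0, s2 * (s2 - 6.0) + 3.0
            # off-diagonal blocks counted once; the kernel is even in u
            scale = 1.0 if j0 == i0 else 2.0
            acc[(4, 0)] += scale * float((he4_1 * w).sum())
            acc[(0, 4)] += scale * float((he4_2 * w).sum())
            acc[(3, 1)] += scale * float((he3_1 * t2 * w).sum())
            acc[(1, 3)] += scale * float((he3_2 * t1 * w).sum())
            acc[(2, 2)] += scale * float((he2_1 * he2_2 * w).sum())
    # (-1)^|r| = +1 for |r| = 4
    return {r: norm * acc[r] / (n * n) for r in _R4}


def _amise(h: np.ndarray, psi: dict, n: int, grad: bool = False):
    """Plug-in AMISE and gradient in (h11, h12, h22) coordinates."""
    h11, h12, h22 = h
    det = h11 * h22 - h12 * h12
    c = 1.0 / (4.0 * np.pi * n)
    t1 = c * det ** -0.5
    p40, p31, p22, p13, p04 = (psi[r] for r in _R4)
    q = (h11 * h11 * p40 + 4 * h11 * h12 * p31 + (2 * h11 * h22 + 4 * h12 * h12) * p22
         + 4 * h12 * h22 * p13 + h22 * h22 * p04)
    val = t1 + 0.25 * q
    if not grad:
        return val
    dt = -0.5 * c * det ** -1.5
    g = np.array([
        dt * h22 + 0.25 * (2 * h11 * p40 + 4 * h12 * p31 + 2 * h22 * p22),
        dt * (-2 * h12) + 0.25 * (4 * h11 * p31 + 8 * h12 * p22 + 4 * h22 * p13),
        dt * h11 + 0.25 * (2 * h11 * p22 + 4 * h12 * p13 + 2 * h22 * p04),
    ])
    return val, g


def _minimize_amise(psi: dict, n: int) -> np.ndarray:
    """Minimize AMISE over SPD H; returns (h11, h12, h22).

    BFGS on the Cholesky log-parametrization (guarantees SPD iterates),
    then a Newton polish directly in (h11, h12, h22) — the Newton map is
    covariant under the linear action of rotations on that coordinate
    triple, which pins down rotation equivariance to machine precision.
    """
    h0 = n ** (-1.0 / 3.0)  # normal-scale start (sphered data)

    def theta_to_h(th):
        l11, l21, l22 = np.exp(th[0]), th[1], np.exp(th[2])
        return np.array([l11 * l11, l11 * l21, l21 * l21 + l22 * l22])

    def obj(th):
        h = theta_to_h(th)
        val, g = _amise(h, psi, n, grad=True)
        l11, l21, l22 = np.exp(th[0]), th[1], np.exp(th[2])
        # d h / d theta (chain through the Cholesky factors)
        jac = np.array([
            [2 * l11 * l11, l11 * l21, 0.0],
            [0.0, l11, 2 * l21],
            [0.0, 0.0, 2 * l22 * l22],
        ])
        return val, jac.T @ g

    th0 = np.array([0.5 * np.log(h0), 0.0, 0.5 * np.log(h0)])
    res = optimize.minimize(obj, th0, jac=True, method="BFGS",
                            options={"gtol": 1e-13, "maxiter": 500})
    h = theta_to_h(res.x)

    for _ in range(60):  # Newton polish with finite-difference Hessian
        val, g = _amise(h, psi, n, grad=True)
        eps = 1e-7 * max(h[0], h[2])
        H2 = np.empty((3, 3))
        for j in range(3):
            hp = h.copy()
            hp[j] += eps
            _, gp = _amise(hp, psi, n, grad=True)
            H2[:, j] = (gp - g) / eps
        H2 = 0.5 * (H2 + H2.T)
        try:
            step = np.linalg.solve(H2, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        h_new = h - step
        if h_new[0] <= 0 or h_new[2] <= 0 or h_new[0] * h_new[2] <= h_new[1] ** 2:
            break
        h = h_new
        if np.linalg.norm(step) < 1e-15 * max(h[0], h[2]):
            break
    return h


def normal_reference_bandwidth(points: np.ndarray) -> np.ndarray:
    """Closed-form normal-scale rule for d=2: H = n^(-1/3) * Sigma_hat."""
    x = np.asarray(points, dtype=float)
    return len(x) ** (-1.0 / 3.0) * np.cov(x.T)


def plugin_bandwidth(points: np.ndarray) -> np.ndarray:
    """Two-stage plug-in estimate of the AMISE-optimal full bandwidth matrix.

    Exactly equivariant under scaling and rotation of the point cloud
    (H -> c^2 H and H -> R H R^T respectively, to floating-point noise).
    Raises for fewer than 8 points or a rank-deficient (collinear) cloud.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    n = len(x)
    if n < MIN_POINTS:
        raise ValueError(f"plugin_bandwidth needs at least {MIN_POINTS} points, got {n}")
    S = np.cov(x.T)
    evals, evecs = np.linalg.eigh(S)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-300):
        raise ValueError(
            "point cloud is (near-)collinear: sample covariance is rank deficient; "
            "a full bandwidth matrix cannot be estimated")
    root = evecs @ np.diag(np.sqrt(evals)) @ evecs.T           # symmetric sqrt
    root_inv = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    z = (x - x.mean(axis=0)) @ root_inv                        # sphered

    g = _pilot_bandwidth(n)
    psi = _psi4_hat(z, g)
    h11, h12, h22 = _minimize_amise(psi, n)
    Hz = np.array([[h11, h12], [h12, h22]])
    H = root @ Hz @ root
    # SPD guarantee: symmetrize and floor eigenvalues
    H = 0.5 * (H + H.T)
    w, v = np.linalg.eigh(H)
    floor = 1e-12 * np.trace(H)
    if w[0] < floor:
        w = np.maximum(w, floor)
        H = v @ np.diag(w) @ v.T
    return H


# ---------------------------------------------------------------------------
# Fingerprint container and pdf evaluation
# ---------------------------------------------------------------------------

@dataclass
class Fingerprint:
    """Gaussian-mixture KDE: support points + one shared 2x2 bandwidth."""

    points: np.ndarray
    H: np.ndarray
    label: str = ""
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if self.H.shape != (2, 2) or not np.allclose(self.H, self.H.T, atol=1e-12):
            raise ValueError("H must be a symmetric 2x2 matrix")
        evals = np.linalg.eigvalsh(self.H)
        if evals[0] <= 0:
            raise ValueError("H must be positive definite")
        self._Hinv = np.linalg.inv(self.H)
        self._norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(self.H)))

    @property
    def n(self) -> int:
        return len(self.points)

    def pdf(self, queries: np.ndarray) -> np.ndarray:
        """Exact Gaussian-mixture density at each query point."""
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        out = np.empty(len(q))
        chunk = max(1, int(4e6 // max(self.n, 1)))
        for s in range(0, len(q), chunk):
            d = q[s:s + chunk, None, :] - self.points[None, :, :]   # (m, N, 2)
            quad = (d @ self._Hinv * d).sum(axis=2)
            out[s:s + chunk] = self._norm * np.exp(-0.5 * quad).mean(axis=1)
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points from the mixture (component choice + Gaussian jitter)."""
        idx = rng.integers(0, self.n, size=n)
        L = np.linalg.cholesky(self.H)
        return self.points[idx] + rng.standard_normal((n, 2)) @ L.T

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Path | str | None = None) -> str:
        obj = {"label": self.label, "kernel": self.kernel,
               "H": self.H.ravel().tolist(),
               "points": self.points.tolist()}
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Path | str) -> "Fingerprint":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        H = np.array(obj["H"], dtype=float).reshape(2, 2)
        return cls(points=np.array(obj["points"], dtype=float), H=H,
                   label=obj.get("label", ""), kernel=obj.get("kernel", "gaussian"))


def fit_fingerprint(embedding: EmbeddingSet,
                    subset: str | Sequence[str] | None = None) -> Fingerprint:
    """Fingerprint of an embedding population (optionally label-filtered).

    All filtered points are used as mixture centers (no train/test split —
    appropriate at the low particle counts typical of these populations),
    with one plug-in bandwidth estimated from the same points.  A union of
    labels gets the union's own bandwidth, never an average of per-label
    bandwidths.
    """
    emb = embedding if subset is None else embedding.filter(subset)
    if emb.coords.shape[0] == 0:
        raise ValueError(f"label filter {subset!r} selected no points")
    if emb.coords.shape[0] < MIN_POINTS:
        raise ValueError(
            f"fingerprint needs at least {MIN_POINTS} points, got {emb.coords.shape[0]}")
    H = plugin_bandwidth(emb.coords)
    label = subset if isinstance(subset, str) else ",".join(sorted(np.unique(emb.labels)))
    return Fingerprint(points=emb.coords.copy(), H=H, label=label)


def kde_pdf(fp: Fingerprint, queries: np.ndarray) -> np.ndarray:
    return fp.pdf(queries)


# ---------------------------------------------------------------------------
# HDR levels, mode, curation
# ---------------------------------------------------------------------------

@dataclass
class HDRLevelSet:
    """Density levels lambda(p) whose super-level sets hold probability p."""

    masses: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        order = np.argsort(self.masses)
        if np.any(np.diff(self.levels[order]) > 0):
            raise ValueError("levels must decrease as mass increases")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"mass": self.masses, "level": self.levels})


def hdr_levels(fp: Fingerprint, masses: Sequence[float],
               points: np.ndarray | None = None) -> HDRLevelSet:
    """Highest-density-region levels via density quantiles at sample points.

    lambda(p) is the (1-p) quantile of the fingerprint density evaluated at
    points distributed according to the fingerprint (by default its own
    support points; pass ``points`` to use a fresh Monte-Carlo sample).
    The region {f >= lambda(p)} then contains probability mass ~ p.
    """
    m = np.asarray(masses, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("masses must lie strictly inside (0, 1)")
    pts = fp.points if points is None else np.asarray(points, dtype=float)
    dens = fp.pdf(pts)
    levels = np.quantile(dens, 1.0 - m)
    return HDRLevelSet(masses=m, levels=levels)


def hdr_mass(fp: Fingerprint, level: float, n: int,
             rng: np.random.Generator) -> float:
    """Monte-Carlo probability mass of the super-level set {f >= level}."""
    samples = fp.sample(n, rng)
    return float(np.mean(fp.pdf(samples) >= level))


@dataclass
class ModeResult:
    point: np.ndarray
    density: float
    tie: bool = False


def global_mode(fp: Fingerprint, tol: float = 1e-6, n_starts: int = 5) -> ModeResult:
    """Global pdf maximum by multi-start shrinking-grid search.

    Starts from the ``n_starts`` highest-density support points and refines
    each on a local 3x3 pattern grid, halving the step until it falls below
    ``tol``.  If two converged maximizers farther than ``tol`` apart have
    densities equal to within a part in 1e12, the first-encountered
    maximizer is returned and the tie is flagged.
    """
    dens = fp.pdf(fp.points)
    order = np.argsort(-dens, kind="stable")[:n_starts]
    step0 = float(np.sqrt(np.linalg.eigvalsh(fp.H)[-1]))
    results = []
    offsets = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)
    for i in order:
        x = fp.points[i].astype(float).copy()
        fx = float(fp.pdf(x[None])[0])
        step = step0
        while step >= tol / 2.0:
            cand = x[None] + step * offsets
            fc = fp.pdf(cand)
            j = int(np.argmax(fc))
            if fc[j] > fx:
                x = cand[j]
                fx = float(fc[j])
            else:
                step *= 0.5
        results.append((x, fx))
    best_idx = int(np.argmax([f for _, f in results]))
    bx, bf = results[best_idx]
    tie = any(
        np.linalg.norm(x - bx) > tol and abs(f - bf) <= 1e-12 * max(bf, 1e-300)
        for k, (x, f) in enumerate(results) if k != best_idx
    )
    return ModeResult(point=bx, density=bf, tie=tie)


def nearest_to_point(embedding: EmbeddingSet, point: np.ndarray,
                     k: int = 50) -> np.ndarray:
    """Indices of the k embeddings closest to ``point`` (ascending distance).

    Exact distance ties are broken by the lower index.
    """
    n = embedding.coords.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of embeddings ({n})")
    d = np.linalg.norm(embedding.coords - np.asarray(point, dtype=float), axis=1)
    order = np.lexsort((np.arange(n), d))
    return order[:k]


def plot_fingerprint(fp: Fingerprint, path: Path | str,
                     masses: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
                     grid: int = 200) -> None:
    """Render HDR contours and the scatter to a PNG/SVG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lv = hdr_levels(fp, masses)
    pad = 3.0 * np.sqrt(np.linalg.eigvalsh(fp.H)[-1])
    lo = fp.points.min(axis=0) - pad
    hi = fp.points.max(axis=0) + pad
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    xx, yy = np.meshgrid(gx, gy)
    zz = fp.pdf(np.column_stack([xx.ravel(), yy.ravel()])).reshape(grid, grid)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(fp.points[:, 0], fp.points[:, 1], s=4, alpha=0.3, color="gray")
    levels = np.sort(lv.levels)
    ax.contour(xx, yy, zz, levels=levels)
    mode = global_mode(fp)
    ax.plot(*mode.point, "x", color="red", markersize=10)
    ax.set_title(fp.label)
    fig.savefig(path, dpi=120)
    plt.close(fig)
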