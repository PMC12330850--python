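"""JZS Bayes factors for pre-specified cue-pattern weight models.

Candidate generalization profiles over the seven cue orientations
(+15..+75 deg; the -45 deg control is outside the weight vectors) are coded
as fixed zero-sum weight contrasts:

* sharpening (lateral inhibition, difference of Gaussians):
  (+0.5, -1, -2, +5, -2, -1, +0.5)
* generalization (quadratic trend): (-3, +0.5, +1.5, +2, +1.5, +0.5, -3)

Each candidate linear mixed model (weight score and/or context indicator as
fixed effects, subjects as random intercepts) is compared against the
random-intercepts-only null with Zellner-Siow priors: a Cauchy scale of 0.5
on standardized fixed slopes and 1.0 on the random-intercept scale, with a
Jeffreys prior on the error variance and grand mean.  Conditional on the
g parameters (slope variance multipliers with inverse-gamma(1/2, r^2/2)
mixing densities, the scale mixture behind the Cauchy) the marginal
likelihood is available in closed form; the g's are integrated numerically
on a tensor Gauss-Legendre grid after mapping each axis onto (0, pi/2) via
g = r^2 tan^2(psi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, roots_legendre

WEIGHT_LEVELS = (15, 25, 35, 45, 55, 65, 75)

R_FIXED = 0.5
R_RANDOM = 1.0
DEFAULT_NODES = 64
CONVERGENCE_TOL = 1e-5


@dataclass(frozen=True)
class WeightModel:
    """A named zero-sum weight vector over the seven cue orientations."""

    name: str
    weights: tuple
    levels: tuple = WEIGHT_LEVELS

    def __post_init__(self):
        if len(self.weights) != len(self.levels):
            raise ValueError("one weight per orientation level required")
        if abs(sum(self.weights)) > 1e-12:
            raise ValueError("weights must sum to zero")

    def score(self, orientation_deg) -> np.ndarray:
        lut = dict(zip(self.levels, self.weights))
        ori = np.asarray(orientation_deg)
        unknown = set(np.unique(ori)) - set(self.levels)
        if unknown:
            raise ValueError(
                f"orientations outside the weight levels: {sorted(unknown)}"
            )
        return np.array([lut[o] for o in ori], dtype=float)


SHARPENING = WeightModel("sharpening", (0.5, -1.0, -2.0, 5.0, -2.0, -1.0, 0.5))
GENERALIZATION = WeightModel(
    "generalization", (-3.0, 0.5, 1.5, 2.0, 1.5, 0.5, -3.0)
)


@dataclass
class DesignSpec:
    """Response vector with centered fixed-effect columns and subject blocks."""

    y: np.ndarray
    X: np.ndarray  # n x p fixed effects of interest (centered)
    Z: np.ndarray | None  # n x n_subjects random-intercept indicators
    fixed_names: tuple


def build_design(
    responses: pd.DataFrame,
    model: WeightModel | None,
    include_context: bool = True,
    value: str = "snr",
) -> DesignSpec:
    """Assemble the mixed-model design from a tidy response table.

    ``responses`` needs columns subject, orientation_deg, context and the
    response value; rows must be restricted to the seven weighted
    orientations.  Fixed columns are the per-cell weight score (if ``model``
    is given) and a centered +/-0.5 context indicator (if
    ``include_context``); subjects enter as random-intercept indicators.
    """
    df = responses.reset_index(drop=True)
    cols = []
    names = []
    if model is not None:
        w = model.score(df["orientation_deg"].to_numpy())
        cols.append(w - w.mean())
        names.append(model.name)
    else:
        # validate the orientation restriction even for context-only models
        SHARPENING.score(df["orientation_deg"].to_numpy())
    if include_context:
        ctx = np.where(df["context"].to_numpy() == "aversive", 0.5, -0.5)
        cols.append(ctx - ctx.mean())
        names.append("context")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    subjects, idx = np.unique(df["subject"].to_numpy(), return_inverse=True)
    Z = np.zeros((len(df), len(subjects)))
    Z[np.arange(len(df)), idx] = 1.0
    return DesignSpec(
        y=df[value].to_numpy(dtype=float), X=X, Z=Z, fixed_names=tuple(names)
    )


class BFConvergenceError(RuntimeError):
    """Raised when the quadrature fails its self-consistency check."""


def _log_marginal_grid(y, blocks, g_grid):
    """log marginal likelihood (up to shared constants) at each g tuple.

    ``blocks`` is a list of column matrices; ``g_grid`` has one g value per
    block and grid point, shape (npts, n_blocks).  Conditional on g the
    coefficients and error variance integrate analytically via the Woodbury
    identity, leaving scalar statistics of the precomputed cross-products.
    """
    n = len(y)
    W = np.hstack(blocks)
    k = W.shape[1]
    sizes = [b.shape[1] for b in blocks]
    col_block = np.repeat(np.arange(len(blocks)), sizes)
    S = W.T @ W
    b_y = W.T @ y
    b_1 = W.sum(axis=0)
    yy = float(y @ y)
    sy = float(y.sum())

    out = np.empty(len(g_grid))
    chunk = max(1, int(2**22 / (k * k)))  # cap the batched workspace
    for lo in range(0, len(g_grid), chunk):
        sq = np.sqrt(g_grid[lo : lo + chunk][:, col_block])  # npts x k
        A = np.eye(k) + sq[:, :, None] * S[None, :, :] * sq[:, None, :]
        L = np.linalg.cholesky(A)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        rhs = np.stack(
            [sq * b_y[None, :], sq * b_1[None, :]], axis=-1
        )  # npts x k x 2
        sol = np.linalg.solve(A, rhs)
        q_yy = np.einsum("pk,pk->p", rhs[..., 0], sol[..., 0])
        q_11 = np.einsum("pk,pk->p", rhs[..., 1], sol[..., 1])
        q_1y = np.einsum("pk,pk->p", rhs[..., 1], sol[..., 0])
        s_yy = yy - q_yy
        s_11 = n - q_11
        s_1y = sy - q_1y
        R = s_yy - s_1y**2 / s_11
        out[lo : lo + chunk] = (
            -0.5 * logdet - 0.5 * np.log(s_11) - 0.5 * (n - 1) * np.log(R)
        )
    return out


def _log_ig_pdf(g, r):
    """log density of the JZS mixing prior g ~ InverseGamma(1/2, r^2/2)."""
    s = r**2 / 2.0
    return 0.5 * np.log(s) - gammaln(0.5) - 1.5 * np.log(g) - s / g


def _log_integral(y, blocks, scales, nodes):
    """log of the g-integrated marginal via tensor Gauss-Legendre.

    Each g axis is mapped onto (0, pi/2) by g = r^2 tan^2(psi); the
    inverse-gamma prior density and the Jacobian enter the log weights.
    """
    if not blocks:
        n = len(y)
        resid = float(y @ y) - y.sum() ** 2 / n
        return -0.5 * np.log(n) - 0.5 * (n - 1) * np.log(resid)
    x, w = roots_legendre(nodes)
    psi = 0.25 * np.pi * (x + 1.0)
    d = len(blocks)
    axis_logw = []
    axis_g = []
    for r in scales:
        g = (r * np.tan(psi)) ** 2
        jac = 2.0 * r**2 * np.tan(psi) / np.cos(psi) ** 2
        axis_logw.append(
            np.log(0.25 * np.pi * w) + _log_ig_pdf(g, r) + np.log(jac)
        )
        axis_g.append(g)
    grids = np.meshgrid(*axis_g, indexing="ij")
    g_grid = np.stack(grids, axis=-1).reshape(-1, d)
    lw = np.zeros(nodes**d)
    for axis in range(d):
        lw += np.meshgrid(*axis_logw, indexing="ij")[axis].ravel()
    logm = _log_marginal_grid(y, blocks, g_grid)
    return float(logsumexp(logm + lw))


def jzs_bf(
    design: DesignSpec,
    r_fixed: float = R_FIXED,
    r_random: float = R_RANDOM,
    nodes: int = DEFAULT_NODES,
    check_convergence: bool = True,
) -> float:
    """Natural-log JZS Bayes factor of the design against its null.

    The alternative holds the fixed effects of interest (standardized, one
    shared g with Cauchy scale ``r_fixed``) plus subject random intercepts
    (own g, scale ``r_random``); the null keeps only the random intercepts.
    A design with no fixed effects equals its null and returns exactly 0.

    Raises
    ------
    BFConvergenceError
        If halving the quadrature order changes the result by more than the
        internal tolerance.
    """
    y = np.asarray(design.y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    p = design.X.shape[1]
    if p == 0:
        return 0.0
    if len(y) <= p:
        raise ValueError("need more rows than fixed effects")
    Xc = design.X - design.X.mean(axis=0)
    rms = np.sqrt((Xc**2).mean(axis=0))
    if np.any(rms == 0):
        raise ValueError("constant fixed-effect column")
    Xs = Xc / rms

    def _bf(nn):
        if design.Z is not None:
            alt = _log_integral(y, [Xs, design.Z], [r_fixed, r_random], nn)
            null = _log_integral(y, [design.Z], [r_random], nn)
        else:
            alt = _log_integral(y, [Xs], [r_fixed], nn)
            null = _log_integral(y, [], [], nn)
        return alt - null

    out = _bf(nodes)
    if check_convergence:
        ref = _bf(max(8, nodes // 2))
        if not np.isfinite(out) or abs(out - ref) > max(
            CONVERGENCE_TOL, 1e-4 * abs(out)
        ):
            raise BFConvergenceError(
                f"quadrature not converged: log BF {out!r} at {nodes} nodes "
                f"vs {ref!r} at {nodes // 2}"
            )
    return float(out)


def jzs_bf_mc(
    design: DesignSpec,
    r_fixed: float = R_FIXED,
    r_random: float = R_RANDOM,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Monte-Carlo cross-check of :func:`jzs_bf` (sampling g from its prior)."""
    y = np.asarray(design.y, dtype=float)
    p = design.X.shape[1]
    if p == 0:
        return 0.0
    Xc = design.X - design.X.mean(axis=0)
    Xs = Xc / np.sqrt((Xc**2).mean(axis=0))
    rng = np.random.default_rng(seed)

    def _mc(blocks, scales):
        if not blocks:
            n = len(y)
            resid = float(y @ y) - y.sum() ** 2 / n
            return -0.5 * np.log(n) - 0.5 * (n - 1) * np.log(resid)
        g = np.stack(
            [r**2 / 2.0 / rng.gamma(0.5, 1.0, size=n_samples) for r in scales],
            axis=-1,
        )
        logm = _log_marginal_grid(y, blocks, g)
        return float(logsumexp(logm) - np.log(n_samples))

    if design.Z is not None:
        return _mc([Xs, design.Z], [r_fixed, r_random]) - _mc(
            [design.Z], [r_random]
        )
    return _mc([Xs], [r_fixed]) - _mc([], [])


@dataclass
class BFMap:
    """Per-sensor natural-log Bayes factors for each model and frequency."""

    table: pd.DataFrame  # columns: sensor, frequency_hz, model, log_bf

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, sensor: str, frequency_hz: float, model: str) -> float:
        t = self.table
        sel = t[
            (t["sensor"] == sensor)
            & (t["frequency_hz"] == frequency_hz)
            & (t["model"] == model)
        ]
        return float(sel["log_bf"].iloc[0])

    def pool_max(self, net, frequency_hz: float, model: str) -> float:
        t = self.table
        sel = t[
            t["sensor"].isin(net.occipital_pool)
            & (t["frequency_hz"] == frequency_hz)
            & (t["model"] == model)
        ]
        return float(sel["log_bf"].max())


def bf_topography(
    snr_by_sensor: pd.DataFrame,
    models=(SHARPENING, GENERALIZATION),
    frequencies=(7.5, 15.0),
    include_context: bool = True,
    nodes: int = DEFAULT_NODES,
) -> BFMap:
    """log Bayes factors per sensor, frequency and candidate model.

    ``snr_by_sensor`` is tidy with columns subject, orientation_deg,
    context, frequency_hz, sensor, snr, restricted to the seven weighted
    orientations.  Cue-pattern models carry the context indicator as an
    additional fixed effect; the "context" model has it as the sole fixed
    effect.  Per-sensor failures are recorded as NaN.
    """
    rows = []
    specs = [(m.name, m, include_context) for m in models]
    specs.append(("context", None, True))
    for f in frequencies:
        sub_f = snr_by_sensor[snr_by_sensor["frequency_hz"] == f]
        for sensor, sub in sub_f.groupby("sensor", sort=False):
            for name, model, with_ctx in specs:
                try:
                    design = build_design(sub, model, include_context=with_ctx)
                    lbf = jzs_bf(design, nodes=nodes)
                except (ValueError, BFConvergenceError):
                    lbf = np.nan
                rows.append((sensor, f, name, lbf))
    return BFMap(
        pd.DataFrame(
            rows, columns=["sensor", "frequency_hz", "model", "log_bf"]
        )
    )
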