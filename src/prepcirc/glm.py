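"""Poisson-GLM encoding model and covariate/type classification of units.

Spike trains are discretized into 1-ms bins.  Event covariates (reward,
lick, visual cue) are delta trains convolved with a raised-cosine temporal
basis (bumps separated by pi/2 radians = 25 ms) spanning a window around the
event (-4..2 s for reward, -2..2 s for lick and cue); running speed enters
as one z-scored continuous column.  A Poisson regression with log link is
fitted; each covariate is then scored by the per-trial coefficient of
determination between its kernel prediction and the smoothed single-trial
PSTH (25-ms Gaussian for licks, 50 ms for reward and speed), with the reward
covariate split into pre ([-4, 0) s) and post ([0, 2) s) sub-windows.  Units
whose mean R^2 across trials exceeds 0.17 for a covariate are classified by
it; the reward sub-window pattern defines type 1 (pre only), type 2 (both)
and type 3 (post only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d

from .errors import InsufficientDataError, PrepcircError
from .session import Session

R2_THRESHOLD = 0.17
DT = 1e-3

DEFAULT_WINDOWS = {"reward": (-4.0, 2.0), "lick": (-2.0, 2.0), "cue": (-2.0, 2.0)}
SMOOTH_SIGMA = {"lick": 0.025}  # all other covariates use 50 ms
DEFAULT_SMOOTH = 0.05


@dataclass
class BasisSpec:
    spacing: float = 0.025           # s between bump centers (pi/2 phase separation)
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    pad: int = 2                     # extra centers beyond each window edge

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise PrepcircError("basis spacing must be > 0")
        for cov, (a, b) in self.windows.items():
            if not (a <= 0.0 <= b) or b - a < self.spacing:
                raise PrepcircError(f"degenerate basis window for {cov!r}")


def raised_cosine_basis(
    window: tuple, spacing: float = 0.025, dt: float = DT, pad: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine bump basis on ``window`` sampled at ``dt``.

    Bump j is b_j(t) = 0.5*(1 + cos(pi*(t - c_j)/(2*spacing))) for
    |t - c_j| <= 2*spacing and 0 elsewhere; centers are spaced ``spacing``
    apart covering the window, extended ``pad`` centers beyond each edge so
    the summed coverage is flat at the boundaries.  Returns (basis matrix of
    shape (n_times, n_bumps), centers).
    """
    a, b = window
    if b - a < spacing:
        raise PrepcircError("window shorter than the bump spacing")
    n_inner = int(round((b - a) / spacing))
    centers = a + spacing * np.arange(-pad, n_inner + pad + 1)
    t = a + dt * np.arange(int(round((b - a) / dt)) + 1)
    arg = (t[:, None] - centers[None, :]) / (2.0 * spacing)
    basis = 0.5 * (1.0 + np.cos(np.pi * arg))
    basis[np.abs(arg) > 1.0] = 0.0
    return basis, centers


@dataclass
class DesignMatrix:
    X: sp.csr_matrix
    columns: dict            # covariate -> slice into X's columns
    centers: dict            # covariate -> bump centers (s, event-relative)
    n_bins: int
    dt: float
    duration: float
    intercept_col: int
    events: dict             # covariate -> event times actually used


def build_design(
    session: Session,
    covariates: tuple = ("reward", "lick", "run"),
    spec: BasisSpec | None = None,
) -> DesignMatrix:
    """Sparse 1-ms design matrix for the requested covariates (+ intercept)."""
    spec = spec or BasisSpec()
    duration = session.duration
    n_bins = int(round(duration / DT))

    blocks: list[sp.csr_matrix] = []
    col_slices: dict[str, slice] = {}
    centers_by_cov: dict[str, np.ndarray] = {}
    events_by_cov: dict[str, np.ndarray] = {}
    col0 = 0

    def _event_times(cov: str) -> np.ndarray:
        if cov == "reward":
            return session.events.reward_times
        if cov == "lick":
            return session.events.lick_times
        if cov.startswith("cue"):
            label = cov.split(":", 1)[1] if ":" in cov else "checkerboard_rewarded"
            return session.events.cue_times.get(label, np.empty(0))
        raise PrepcircError(f"unknown event covariate {cov!r}")

    for cov in covariates:
        if cov == "run":
            continue
        ev = _event_times(cov)
        if ev.size == 0:
            warnings.warn(f"covariate {cov!r} has no events; omitted", stacklevel=2)
            continue
        wkey = "cue" if cov.startswith("cue") else cov
        window = spec.windows.get(wkey, spec.windows.get(cov, (-2.0, 2.0)))
        _, centers = raised_cosine_basis(window, spec.spacing, DT, spec.pad)
        half = int(round(2.0 * spec.spacing / DT))
        offs = np.arange(-half, half + 1)
        vals = 0.5 * (1.0 + np.cos(np.pi * offs * DT / (2.0 * spec.spacing)))
        vals[np.abs(offs * DT) > 2.0 * spec.spacing] = 0.0
        ev_bins = np.round(ev / DT).astype(np.int64)
        c_bins = np.round(centers / DT).astype(np.int64)
        n_bumps = centers.size
        parts = []
        chunk = max(1, 2_000_000 // (n_bumps * offs.size))
        for s in range(0, ev_bins.size, chunk):
            eb = ev_bins[s : s + chunk]
            rows = (eb[:, None, None] + c_bins[None, :, None] + offs[None, None, :]).ravel()
            cols = np.broadcast_to(
                np.arange(n_bumps)[None, :, None], (eb.size, n_bumps, offs.size)
            ).ravel()
            data = np.broadcast_to(vals[None, None, :], (eb.size, n_bumps, offs.size)).ravel()
            ok = (rows >= 0) & (rows < n_bins)
            parts.append(
                sp.coo_matrix(
                    (data[ok], (rows[ok], cols[ok])), shape=(n_bins, n_bumps)
                ).tocsr()
            )
        block = parts[0]
        for p in parts[1:]:
            block = block + p
        blocks.append(block)
        col_slices[cov] = slice(col0, col0 + n_bumps)
        centers_by_cov[cov] = centers
        events_by_cov[cov] = ev
        col0 += n_bumps

    if "run" in covariates:
        t = (np.arange(n_bins) + 0.5) * DT
        speed = np.interp(t, session.behavior.times, session.behavior.running_speed)
        z = (speed - speed.mean()) / max(speed.std(), 1e-12)
        blocks.append(sp.csr_matrix(z[:, None]))
        col_slices["run"] = slice(col0, col0 + 1)
        col0 += 1

    blocks.append(sp.csr_matrix(np.ones((n_bins, 1))))
    intercept_col = col0
    col_slices["intercept"] = slice(col0, col0 + 1)
    X = sp.hstack(blocks, format="csr")
    return DesignMatrix(X, col_slices, centers_by_cov, n_bins, DT, duration, intercept_col, events_by_cov)


def bin_spikes(spikes: np.ndarray, n_bins: int, dt: float = DT) -> np.ndarray:
    y = np.zeros(n_bins)
    idx = np.clip((np.asarray(spikes) / dt).astype(int), 0, n_bins - 1)
    np.add.at(y, idx, 1.0)
    return y


@dataclass
class PoissonFitResult:
    weights: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    grad_norm: float


def fit_poisson(
    X,
    y: np.ndarray,
    ridge: float = 1e-4,
    intercept_col: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    raise_on_failure: bool = True,
) -> PoissonFitResult:
    """Poisson regression with log link, maximized by damped Newton (IRLS).

    A small ridge penalty on all non-intercept weights keeps the problem
    well posed for rank-deficient or all-zero-response designs.  ``X`` may be
    dense or scipy-sparse; convergence is declared when the max-norm of the
    penalized gradient drops below ``tol`` times a problem scale
    (max(1, sum(y))).
    """
    sparse = sp.issparse(X)
    if sparse:
        X = X.tocsr()
    else:
        X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    pen = np.full(p, ridge)
    if intercept_col is not None:
        pen[intercept_col] = 0.0

    beta = np.zeros(p)
    if intercept_col is not None:
        beta[intercept_col] = np.log(max(y.mean(), 1e-10))

    scale = max(1.0, y.sum())

    def _eta(b):
        return np.clip(np.asarray(X @ b).ravel(), -30.0, 3.0)

    def _pll(b):
        eta = _eta(b)
        return float(y @ eta - np.exp(eta).sum() - 0.5 * np.sum(pen * b * b))

    ll = _pll(beta)
    converged = False
    it = 0
    gnorm = np.inf
    for it in range(1, max_iter + 1):
        eta = _eta(beta)
        mu = np.exp(eta)
        grad = np.asarray(X.T @ (y - mu)).ravel() - pen * beta
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * scale:
            converged = True
            break
        w = np.sqrt(mu)
        if sparse:
            Xw = X.multiply(w[:, None]).tocsr()
            H = (Xw.T @ Xw).toarray()
        else:
            H = X.T @ (mu[:, None] * X)
        H[np.diag_indices_from(H)] += pen + 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.diag(H) + 1e-8)
        # backtracking line search on the penalized log-likelihood
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            llc = _pll(cand)
            if llc >= ll - 1e-12:
                beta, ll = cand, llc
                break
            alpha *= 0.5
        else:
            break
        if alpha * float(np.max(np.abs(step))) < 1e-10:
            converged = True
            break
    if not converged and raise_on_failure and y.sum() > 0:
        raise PrepcircError(
            f"Poisson fit did not converge in {max_iter} iterations "
            f"(grad max {gnorm:.3g}, scale {scale:.3g})"
        )
    return PoissonFitResult(beta, converged, it, ll, gnorm)


# ---------------------------------------------------------------------------
# scoring and classification


def _linfit_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the simple linear regression of y on x (slope + intercept)."""
    sx = x - x.mean()
    sy = y - y.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vy <= 1e-300:
        return 1.0  # constant response is fit exactly by any line
    if vx <= 1e-300:
        return 0.0
    c = float(sx @ sy)
    return c * c / (vx * vy)


def _smoothed_trial_rate(y: np.ndarray, i0: int, i1: int, sigma_bins: float) -> np.ndarray:
    """Smoothed spike counts (Hz) on bins [i0, i1), padded to avoid edge bias."""
    pad = int(np.ceil(4 * sigma_bins))
    a = max(i0 - pad, 0)
    b = min(i1 + pad, y.size)
    seg = gaussian_filter1d(y[a:b], sigma_bins, mode="constant") / DT
    return seg[i0 - a : i0 - a + (i1 - i0)]


@dataclass
class GlmFit:
    """Weights plus per-trial/mean R^2 per covariate (reward split pre/post)."""

    weights: dict
    r2: dict                 # covariate (or 'reward_pre'/'reward_post') -> per-trial array
    mean_r2: dict
    design: DesignMatrix


def score_fit(
    fitres: PoissonFitResult,
    design: DesignMatrix,
    session: Session,
    spikes: np.ndarray,
    spec: BasisSpec | None = None,
) -> GlmFit:
    """Per-trial R^2 of each covariate's kernel prediction vs the smoothed PSTH."""
    spec = spec or BasisSpec()
    y = bin_spikes(spikes, design.n_bins)
    beta = fitres.weights
    weights = {cov: beta[sl] for cov, sl in design.columns.items()}
    r2: dict[str, list] = {}

    trials = session.trials
    trial_edges = np.append(trials.start_time, design.duration)

    for cov, sl in design.columns.items():
        if cov == "intercept":
            continue
        sigma = SMOOTH_SIGMA.get(cov, DEFAULT_SMOOTH) / DT
        if cov == "run":
            t = (np.arange(design.n_bins) + 0.5) * DT
            speed = np.interp(t, session.behavior.times, session.behavior.running_speed)
            scores = []
            for k in range(len(trials)):
                i0 = int(trial_edges[k] / DT)
                i1 = min(int(trial_edges[k + 1] / DT), design.n_bins)
                if i1 - i0 < 100:
                    continue
                psth = _smoothed_trial_rate(y, i0, i1, sigma)
                scores.append(_linfit_r2(speed[i0:i1], psth))
            r2["run"] = scores
            continue

        wkey = "cue" if cov.startswith("cue") else cov
        window = spec.windows.get(wkey, (-2.0, 2.0))
        basis, _ = raised_cosine_basis(window, spec.spacing, DT, spec.pad)
        kernel = basis @ beta[sl]
        a = window[0]
        ev = design.events[cov]

        if cov == "lick":
            # many events per trial: superpose kernels, score over the trial span
            pred_full = np.zeros(design.n_bins)
            k0 = int(round(a / DT))
            for e in ev:
                i = int(round(e / DT)) + k0
                j0, j1 = max(i, 0), min(i + kernel.size, design.n_bins)
                if j1 > j0:
                    pred_full[j0:j1] += kernel[j0 - i : j1 - i]
            scores = []
            for k in range(len(trials)):
                i0 = int(trial_edges[k] / DT)
                i1 = min(int(trial_edges[k + 1] / DT), design.n_bins)
                if i1 - i0 < 100 or not np.any((ev >= trial_edges[k]) & (ev < trial_edges[k + 1])):
                    continue
                psth = _smoothed_trial_rate(y, i0, i1, sigma)
                scores.append(_linfit_r2(pred_full[i0:i1], psth))
            r2["lick"] = scores
            continue

        # one event per trial (reward, cue): score over the covariate window
        subwins = {cov: (0, kernel.size)}
        if cov == "reward":
            split = int(round(-a / DT))
            subwins = {"reward_pre": (0, split), "reward_post": (split, kernel.size),
                       "reward": (0, kernel.size)}
        scores_by = {k: [] for k in subwins}
        for e in ev:
            i = int(round((e + a) / DT))
            if i < 0 or i + kernel.size > design.n_bins:
                continue
            psth = _smoothed_trial_rate(y, i, i + kernel.size, sigma)
            for name, (j0, j1) in subwins.items():
                scores_by[name].append(_linfit_r2(kernel[j0:j1], psth[j0:j1]))
        for name, vals in scores_by.items():
            r2[name] = vals

    r2_arr = {k: np.asarray(v, dtype=float) for k, v in r2.items()}
    mean_r2 = {k: (float(np.mean(v)) if v.size else float("nan")) for k, v in r2_arr.items()}
    return GlmFit(weights=weights, r2=r2_arr, mean_r2=mean_r2, design=design)


@dataclass
class UnitClassification:
    unit_id: str
    classes: list            # covariates whose mean R^2 exceeds the threshold
    unit_type: int           # 1, 2, 3 or 0 (none)
    sign_pre: int            # +1 increasing / -1 decreasing in [-1, 0) s
    sign_post: int
    mean_r2: dict


def classify_unit(
    fit: GlmFit,
    psth_z_mean: np.ndarray | None = None,
    psth_bin_centers: np.ndarray | None = None,
    unit_id: str = "",
    threshold: float = R2_THRESHOLD,
) -> UnitClassification:
    """Covariate classes and type 1/2/3 from mean per-trial R^2 (strict > threshold)."""
    passed = {k: (np.isfinite(v) and v > threshold) for k, v in fit.mean_r2.items()}
    pre = passed.get("reward_pre", False)
    post = passed.get("reward_post", False)
    if pre and post:
        unit_type = 2
    elif pre:
        unit_type = 1
    elif post:
        unit_type = 3
    else:
        unit_type = 0
    classes = [
        k for k, ok in passed.items() if ok and k not in ("reward_pre", "reward_post")
    ]
    if (pre or post) and "reward" not in classes:
        classes.append("reward")

    sign_pre = sign_post = 0
    if psth_z_mean is not None and psth_bin_centers is not None:
        c = psth_bin_centers
        m_pre = (c >= -1.0) & (c < 0.0)
        m_post = (c >= 0.0) & (c < 1.0)
        if m_pre.any():
            sign_pre = 1 if float(psth_z_mean[m_pre].mean()) >= 0 else -1
        if m_post.any():
            sign_post = 1 if float(psth_z_mean[m_post].mean()) >= 0 else -1
    return UnitClassification(unit_id, sorted(classes), unit_type, sign_pre, sign_post, dict(fit.mean_r2))


def classify_session_units(
    session: Session,
    unit_ids=None,
    covariates: tuple = ("reward", "lick", "run"),
    spec: BasisSpec | None = None,
    ridge: float = 1e-4,
    min_spikes: int = 20,
) -> dict[str, UnitClassification]:
    """Fit + score + classify every requested unit against one shared design."""
    from .rates import RateTrace, align_psth, estimate_rate, zscore, zscore_psth, ZScoreParams

    spec = spec or BasisSpec()
    design = build_design(session, covariates, spec)
    out: dict[str, UnitClassification] = {}
    ids = unit_ids if unit_ids is not None else [u.unit_id for u in session.units]
    for uid in ids:
        spikes = session.spikes[uid]
        if spikes.size < min_spikes:
            raise InsufficientDataError(f"unit {uid!r} has fewer than {min_spikes} spikes")
        y = bin_spikes(spikes, design.n_bins)
        fres = fit_poisson(
            design.X, y, ridge=ridge, intercept_col=design.intercept_col, raise_on_failure=False
        )
        fit = score_fit(fres, design, session, spikes, spec)
        trace = estimate_rate(spikes, session.duration, unit_id=uid)
        z, _ = zscore(trace.rate)
        ztr = RateTrace(z, trace.fs, 0.0, trace.kernel_sigma, uid)
        try:
            psth = align_psth(ztr, session.events.reward_times, (-4.0, 2.0), 0.05, "reward")
            out[uid] = classify_unit(fit, psth.mean(), psth.bin_centers, uid)
        except Exception:
            out[uid] = classify_unit(fit, None, None, uid)
    return out
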