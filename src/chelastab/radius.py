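"""Gaussian analysis of paired bond-length differences and ionic-radius estimation.

The bond distances of a larger trivalent ion's coordination sphere are
systematically longer than those of a smaller analogue in the same chelator.
Pooling the per-donor differences delta_d over many complex pairs gives a
distribution whose center measures the ionic-radius difference between the two
ions.  Amine-nitrogen donors sit on flat potential-energy surfaces and smear
that distribution, so the analysis supports an amine-excluding subset whose
single-Gaussian center is the radius-difference estimate:

    r(cmp ion) = r(reference ion, same CN) + center.

Two fitting routes are provided: unbinned maximum likelihood (EM for two
components) — the default, because it needs no bin-width choice — and binned
least squares against histogram counts for figure parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ChelastabError, ConvergenceError, EmptySelectionError, SingularComponentError
from .geometry import ContactPair

logger = logging.getLogger(__name__)

SHANNON_LA3_CN9 = 1.216  # Angstrom, Shannon crystal radius-derived ionic radius
WIDTH_FLOOR_A = 1e-4

SUBSETS = ("all", "excluding_amine", "amine_only")


@dataclass(frozen=True)
class DeltaDistanceSet:
    """Pooled delta_d values with their donor-class tags and subset flag."""

    values: np.ndarray
    tags: tuple[str, ...]
    subset: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.tags):
            raise ChelastabError("values and tags must be parallel 1-D sequences")
        if self.subset not in SUBSETS:
            raise ChelastabError(f"unknown subset {self.subset!r}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GaussianFit:
    """Fitted 1- or 2-component Gaussian model of a delta_d sample.

    ``centers``/``widths``/``weights``/``center_se`` are per component;
    for two components the centers are reported in ascending order.
    ``loglik`` is the unbinned log-likelihood for MLE fits and the negative
    residual sum of squares for binned least squares.
    """

    n_components: int
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    weights: tuple[float, ...]
    center_se: tuple[float, ...]
    loglik: float
    method: str
    n_obs: int

    def __post_init__(self):
        if self.n_components not in (1, 2):
            raise ChelastabError("n_components must be 1 or 2")
        if any(w <= 0 for w in self.widths):
            raise ChelastabError("widths must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9 or any(
            not (0 < w <= 1) for w in self.weights
        ):
            raise ChelastabError("weights must lie in (0, 1] and sum to 1")
        if self.n_components == 2 and self.centers[0] > self.centers[1]:
            raise ChelastabError("two-component centers must be ascending")

    def summary(self) -> str:
        lines = [
            f"Gaussian fit ({self.method}), {self.n_components} component(s), "
            f"n = {self.n_obs}",
            f"{'comp':>4} {'center/A':>10} {'se/A':>8} {'width/A':>9} {'weight':>8}",
        ]
        for k in range(self.n_components):
            lines.append(
                f"{k:>4} {self.centers[k]:>10.4f} {self.center_se[k]:>8.4f} "
                f"{self.widths[k]:>9.4f} {self.weights[k]:>8.3f}"
            )
        lines.append(f"loglik = {self.loglik:.3f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RadiusEstimate:
    """Ionic radius transferred from a reference ion via a fitted delta_d center.

    The quoted spread is the fitted component width (the physical scatter of
    the distance differences), not the much smaller standard error of the
    center, which is carried separately.
    """

    r_reference: float
    center: float
    spread: float
    center_se: float

    @property
    def r_estimated(self) -> float:
        return self.r_reference + self.center

    def __str__(self) -> str:
        return (
            f"r = {self.r_estimated:.3f} +/- {self.spread:.3f} A "
            f"(reference {self.r_reference:.3f} + center {self.center:.3f}, "
            f"center se {self.center_se:.3f})"
        )


# ---------------------------------------------------------------------------


def collect_deltas(pairs: Sequence[ContactPair], subset: str = "all") -> DeltaDistanceSet:
    """Pool contact-pair deltas, optionally partitioned on the amine-N class."""
    if not pairs:
        raise EmptySelectionError("no contact pairs supplied")
    if subset not in SUBSETS:
        raise ChelastabError(f"unknown subset {subset!r}")
    if subset == "all":
        keep = list(pairs)
    elif subset == "excluding_amine":
        keep = [p for p in pairs if p.donor_class != "N_amine"]
    else:
        keep = [p for p in pairs if p.donor_class == "N_amine"]
    if not keep:
        raise EmptySelectionError(f"subset {subset!r} is empty")
    counts: dict[str, int] = {}
    for p in keep:
        counts[p.donor_class] = counts.get(p.donor_class, 0) + 1
    logger.info("collect_deltas(%s): %s", subset, counts)
    return DeltaDistanceSet(
        values=np.array([p.delta for p in keep]),
        tags=tuple(p.donor_class for p in keep),
        subset=subset,
    )


def _as_values(data) -> np.ndarray:
    if isinstance(data, DeltaDistanceSet):
        return np.asarray(data.values, dtype=float)
    return np.asarray(data, dtype=float)


def _loglik(x: np.ndarray, mu, sig, w) -> float:
    dens = np.zeros_like(x)
    for m, s, wk in zip(mu, sig, w):
        dens += wk * stats.norm.pdf(x, m, s)
    return float(np.sum(np.log(dens)))


def _numeric_center_se(x: np.ndarray, mu, sig, w) -> tuple[float, ...]:
    """Center SEs from the observed information (central-difference Hessian).

    Parameters are (mu_1..mu_K, log sig_1..K, [logit w_1 for K=2]); the SEs
    reported are the mu entries of the inverse Hessian.
    """
    k = len(mu)
    if k == 1:
        # analytic: observed information for a normal mean is n / sigma^2
        return (float(sig[0] / np.sqrt(len(x))),)

    def unpack(theta):
        m = theta[:2]
        s = np.exp(theta[2:4])
        p = 1.0 / (1.0 + np.exp(-theta[4]))
        return m, s, (p, 1.0 - p)

    def nll(theta):
        m, s, ww = unpack(theta)
        return -_loglik(x, m, s, ww)

    w0 = min(max(w[0], 1e-6), 1 - 1e-6)
    theta0 = np.array([mu[0], mu[1], np.log(sig[0]), np.log(sig[1]),
                       np.log(w0 / (1 - w0))])
    n = len(theta0)
    h = 1e-4 * np.maximum(np.abs(theta0), 1.0)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            f_pp = nll(theta0 + ei + ej)
            f_pm = nll(theta0 + ei - ej)
            f_mp = nll(theta0 - ei + ej)
            f_mm = nll(theta0 - ei - ej)
            hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov)[:2], 0.0))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("observed information singular; falling back to sig/sqrt(n_k)")
        n_eff = np.array([max(wk * len(x), 1.0) for wk in w])
        se = np.array(sig) / np.sqrt(n_eff)
    return tuple(float(v) for v in se)


def _fit_mle(x: np.ndarray, n_components: int, max_iter: int, tol: float) -> GaussianFit:
    n = len(x)
    if n_components == 1:
        mu = float(np.mean(x))
        sig = float(np.std(x))
        if sig < WIDTH_FLOOR_A:
            raise SingularComponentError(
                f"fitted width {sig:.2e} A below floor {WIDTH_FLOOR_A} A"
            )
        return GaussianFit(
            1, (mu,), (sig,), (1.0,), (sig / np.sqrt(n),),
            _loglik(x, [mu], [sig], [1.0]), "mle", n,
        )

    # EM, initialized by a median split (deterministic, seed-independent)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(lo) < 2 or len(hi) < 2:
        raise SingularComponentError("median split leaves a component with < 2 points")
    mu = np.array([lo.mean(), hi.mean()])
    sig = np.array([max(lo.std(), WIDTH_FLOOR_A * 10), max(hi.std(), WIDTH_FLOOR_A * 10)])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for it in range(max_iter):
        resp = np.stack([wk * stats.norm.pdf(x, m, s) for m, s, wk in zip(mu, sig, w)])
        tot = resp.sum(axis=0)
        resp /= tot
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp @ x) / nk
        sig = np.sqrt(np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)]))
        if np.any(sig < WIDTH_FLOOR_A):
            raise SingularComponentError(
                f"component width collapsed below {WIDTH_FLOOR_A} A at iteration {it}"
            )
        ll = _loglik(x, mu, sig, w)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    else:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations",
            last_iterate={"centers": mu.tolist(), "widths": sig.tolist(),
                          "weights": w.tolist(), "loglik": ll},
        )
    if abs(mu[0] - mu[1]) < 1e-9:
        raise SingularComponentError("both components converged to the same center")
    order = np.argsort(mu)
    mu, sig, w = mu[order], sig[order], w[order]
    se = _numeric_center_se(x, mu, sig, w)
    return GaussianFit(
        2, tuple(mu), tuple(sig), tuple(w), se, ll, "mle", n,
    )


def _fit_binned(x: np.ndarray, n_components: int, bin_width: float) -> GaussianFit:
    if bin_width <= 0:
        raise ChelastabError("bin_width must be positive")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2

    if n_components == 1:
        p0 = [len(x) * bin_width / (np.std(x) * np.sqrt(2 * np.pi)),
              float(np.mean(x)), max(float(np.std(x)), bin_width)]

        def model(t, a, m, s):
            return a * np.exp(-((t - m) ** 2) / (2 * s**2))
    else:
        med = np.median(x)
        lo_v, hi_v = x[x <= med], x[x > med]
        amp = len(x) * bin_width / (np.std(x) * np.sqrt(2 * np.pi)) / 2
        p0 = [amp, float(lo_v.mean()), max(float(lo_v.std()), bin_width),
              amp, float(hi_v.mean()), max(float(hi_v.std()), bin_width)]

        def model(t, a1, m1, s1, a2, m2, s2):
            return a1 * np.exp(-((t - m1) ** 2) / (2 * s1**2)) + a2 * np.exp(
                -((t - m2) ** 2) / (2 * s2**2)
            )

    try:
        popt, pcov = optimize.curve_fit(model, mids, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ConvergenceError(f"binned least squares failed: {exc}", last_iterate=p0)
    perr = np.sqrt(np.abs(np.diag(pcov)))
    if n_components == 1:
        a, m, s = popt
        s = abs(s)
        if s < WIDTH_FLOOR_A:
            raise SingularComponentError("binned fit width collapsed")
        mass = (abs(a) * s,)
        centers, widths, ses = (m,), (s,), (float(perr[1]),)
        weights = (1.0,)
    else:
        a1, m1, s1, a2, m2, s2 = popt
        s1, s2 = abs(s1), abs(s2)
        if min(s1, s2) < WIDTH_FLOOR_A:
            raise SingularComponentError("binned fit width collapsed")
        if abs(m1 - m2) < 1e-9:
            raise SingularComponentError("binned fit centers coincide")
        comps = sorted(
            [(m1, s1, abs(a1) * s1, float(perr[1])), (m2, s2, abs(a2) * s2, float(perr[4]))]
        )
        mass_tot = comps[0][2] + comps[1][2]
        centers = (comps[0][0], comps[1][0])
        widths = (comps[0][1], comps[1][1])
        weights = (comps[0][2] / mass_tot, comps[1][2] / mass_tot)
        ses = (comps[0][3], comps[1][3])
    resid = counts - model(mids, *popt)
    return GaussianFit(
        n_components, centers, widths, weights, ses,
        -float(np.sum(resid**2)), "binned_ls", len(x),
    )


def fit_gaussians(
    data,
    n_components: int = 1,
    method: str = "mle",
    bin_width: float = 0.01,
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> GaussianFit:
    """Fit a 1- or 2-component Gaussian model to a delta_d sample.

    ``method="mle"`` fits unbinned maximum likelihood (EM for two
    components, median-split initialization); ``method="binned_ls"``
    fits Gaussian curves to histogram counts at ``bin_width`` (default
    0.01 A).  Requires at least ``5 * n_components`` points.
    """
    x = _as_values(data)
    if n_components not in (1, 2):
        raise ChelastabError("n_components must be 1 or 2")
    if len(x) < 5 * n_components:
        raise ChelastabError(
            f"need >= {5 * n_components} points for {n_components} component(s), "
            f"got {len(x)}"
        )
    if method == "mle":
        return _fit_mle(x, n_components, max_iter, tol)
    if method == "binned_ls":
        return _fit_binned(x, n_components, bin_width)
    raise ChelastabError(f"unknown method {method!r}")


def estimate_radius(
    fit: GaussianFit, component: int = 0, r_reference: float = SHANNON_LA3_CN9
) -> RadiusEstimate:
    """Transfer an ionic radius: r_estimated = r_reference + fitted center."""
    if not 0 <= component < fit.n_components:
        raise ChelastabError(
            f"component {component} invalid for a {fit.n_components}-component fit"
        )
    return RadiusEstimate(
        r_reference=r_reference,
        center=fit.centers[component],
        spread=fit.widths[component],
        center_se=fit.center_se[component],
    )
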