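"""TCSPC decay simulation and mono/bi-exponential fitting.

Time-domain FLIM histograms photon arrival times after pulsed excitation
into fixed-width bins (80 ps here).  A decay that is a mixture of
exponentials with intensity fractions ``a_i`` and lifetimes ``τ_i`` puts an
expected fraction ``Σ a_i (e^{−t₀/τ_i} − e^{−t₁/τ_i})`` of the photons into
the bin [t₀, t₁]; observed counts are Poisson around that expectation.

Fitting conventions
-------------------
* Mono-exponential fits (`fit_monoexp`) maximise the Poisson likelihood of
  ``A e^{−t/τ} + b`` — exact for counting noise, and unbiased down to low
  counts where weighted least squares is not.
* Bi-exponential fits (`fit_biexp`) minimise Neyman-weighted least squares
  with the two amplitudes *unconstrained in sign*.  This is deliberate: a
  decay that is truly mono-exponential can often only support a second
  component with a negative amplitude, which is physically impossible, and
  leaving the sign free makes that failure mode detectable rather than
  hiding it behind a bound.
* `select_decay_model` prefers the bi-exponential fit only when it is
  physical (non-negative amplitudes, positive lifetimes) *and* improves the
  reduced χ² by more than a threshold; otherwise the mono fit is kept.

The reduced χ² reported by both fits is Neyman-weighted,
``Σ (c−m)²/max(c,1) / (n_bins − n_params)``, for comparability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DecayHistogram",
    "DecayFit",
    "simulate_decay",
    "expected_decay_histogram",
    "fit_monoexp",
    "fit_biexp",
    "select_decay_model",
]

DEFAULT_BIN_WIDTH_PS = 80.0
DEFAULT_WINDOW_NS = 12.5  # 80 MHz repetition period


@dataclass(frozen=True)
class DecayHistogram:
    """A TCSPC arrival-time histogram."""

    counts: np.ndarray
    bin_width_ps: float = DEFAULT_BIN_WIDTH_PS
    window_ns: float = DEFAULT_WINDOW_NS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-d array with >= 2 bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_edges_ns(self) -> np.ndarray:
        n = self.counts.size
        return np.arange(n + 1) * self.bin_width_ps * 1e-3

    @property
    def bin_centers_ns(self) -> np.ndarray:
        edges = self.bin_edges_ns
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class DecayFit:
    """Result of an exponential decay fit.

    ``taus`` are sorted descending; ``fractions`` are the matching
    amplitude fractions ``A_i / Σ A_j`` (they sum to 1 but individual
    entries may be negative for non-physical bi-exponential solutions).
    """

    n_components: int
    taus: tuple[float, ...]
    fractions: tuple[float, ...]
    amplitudes: tuple[float, ...]
    background: float
    reduced_chisq: float
    physical: bool
    stderr: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("amplitude fractions must sum to 1")


def _check_components(
    components: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    comps = np.asarray(components, dtype=float)
    if comps.ndim != 2 or comps.shape[1] != 2:
        raise ValueError("components must be a sequence of (fraction, tau_ns)")
    fracs, taus = comps[:, 0], comps[:, 1]
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    return fracs, taus


def expected_decay_histogram(
    components: Sequence[tuple[float, float]],
    total_photons: float,
    bin_width_ps: float = DEFAULT_BIN_WIDTH_PS,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> DecayHistogram:
    """Noise-free expected histogram (float counts), exact per-bin integrals.

    Expected counts are scaled so they sum to ``total_photons``.
    """
    fracs, taus = _check_components(components)
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    if window_ns < 3.0 * taus.max():
        warnings.warn(
            f"window {window_ns} ns < 3x the longest lifetime "
            f"{taus.max()} ns: truncation bias likely",
            stacklevel=2,
        )
    n_bins = int(round(window_ns * 1e3 / bin_width_ps))
    edges = np.arange(n_bins + 1) * bin_width_ps * 1e-3  # ns
    p = np.zeros(n_bins)
    for a, tau in zip(fracs, taus):
        surv = np.exp(-edges / tau)
        p += a * (surv[:-1] - surv[1:])
    expected = p * (total_photons / p.sum())
    return DecayHistogram(expected, bin_width_ps=bin_width_ps, window_ns=window_ns)


def simulate_decay(
    components: Sequence[tuple[float, float]],
    total_photons: int,
    bin_width_ps: float = DEFAULT_BIN_WIDTH_PS,
    window_ns: float = DEFAULT_WINDOW_NS,
    rng: np.random.Generator | int | None = None,
) -> DecayHistogram:
    """Poisson-noise TCSPC histogram of a known decay, deterministic by seed."""
    expected = expected_decay_histogram(
        components, total_photons, bin_width_ps=bin_width_ps, window_ns=window_ns
    )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    counts = gen.poisson(expected.counts).astype(float)
    return DecayHistogram(counts, bin_width_ps=bin_width_ps, window_ns=window_ns)


def _neyman_reduced_chisq(
    counts: np.ndarray, model: np.ndarray, n_params: int
) -> float:
    w = np.maximum(counts, 1.0)
    dof = max(counts.size - n_params, 1)
    return float(np.sum((counts - model) ** 2 / w) / dof)


def _loglinear_init(t: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Amplitude/lifetime initial guess from count-weighted log-linear fit."""
    mask = counts > 0
    if mask.sum() < 2:
        return max(counts.max(), 1.0), 1.0
    y = np.log(counts[mask])
    w = counts[mask]
    coeffs = np.polyfit(t[mask], y, 1, w=np.sqrt(w))
    slope, intercept = coeffs[0], coeffs[1]
    tau = -1.0 / slope if slope < 0 else 10.0
    return float(np.exp(intercept)), float(min(max(tau, 1e-3), 1e3))


def fit_monoexp(hist: DecayHistogram, fit_background: bool = False) -> DecayFit:
    """Poisson maximum-likelihood fit of A·exp(−t/τ) (+ b) to a histogram.

    ``fit_background`` adds a flat background term b ≥ 0.  It is off by
    default: the simulator models delta excitation with negligible dark
    counts, and fitting a boundary-constrained background to
    background-free data biases τ̂ low at finite photon counts.  Enable it
    for data that genuinely contains uncorrelated counts.
    """
    counts = hist.counts
    if hist.total_photons < 1000:
        warnings.warn(
            f"only {hist.total_photons:.0f} photons: fit attempted but "
            "estimates will be noisy",
            stacklevel=2,
        )
    t = hist.bin_centers_ns
    a0, tau0 = _loglinear_init(t, counts)

    def model(theta: np.ndarray) -> np.ndarray:
        a, tau = theta[0], theta[1]
        b = theta[2] if fit_background else 0.0
        return a * np.exp(-t / tau) + b

    def nll(theta: np.ndarray) -> float:
        m = model(theta)
        if np.any(m <= 0):
            return 1e300
        return float(np.sum(m - counts * np.log(m)))

    def grad(theta: np.ndarray) -> np.ndarray:
        a, tau = theta[0], theta[1]
        decay = np.exp(-t / tau)
        m = model(theta)
        if np.any(m <= 0):
            return np.zeros(theta.size)
        w = 1.0 - counts / m
        g = [float(np.sum(w * decay)), float(np.sum(w * a * decay * t / tau**2))]
        if fit_background:
            g.append(float(np.sum(w)))
        return np.array(g)

    bounds = [(1e-12, None), (1e-4, 1e4)]
    x0 = [a0, tau0]
    if fit_background:
        bounds.append((1e-12, None))
        x0.append(max(counts.min(), 1e-3))
    x0 = np.array(x0)
    res = minimize(
        nll,
        x0,
        jac=grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"mono-exponential fit failed: {res.message}")
    a_hat, tau_hat = res.x[0], res.x[1]
    b_hat = res.x[2] if fit_background else 0.0
    names = ("amplitude", "tau", "background") if fit_background else ("amplitude", "tau")
    stderr = _mle_stderr(nll, res.x, names=names)
    # a fit dominated by background, or with a lifetime far beyond the
    # window, carries no decay information
    decay_photons = a_hat * tau_hat / (hist.bin_width_ps * 1e-3)
    physical = bool(
        tau_hat < 2.0 * hist.window_ns
        and decay_photons > 0.01 * max(hist.total_photons, 1.0)
    )
    return DecayFit(
        n_components=1,
        taus=(float(tau_hat),),
        fractions=(1.0,),
        amplitudes=(float(a_hat),),
        background=float(b_hat),
        reduced_chisq=_neyman_reduced_chisq(counts, model(res.x), res.x.size),
        physical=physical,
        stderr=stderr,
    )


def _mle_stderr(
    nll, x_opt: np.ndarray, names: Sequence[str]
) -> dict[str, float | None]:
    """Parameter standard errors from a finite-difference Hessian of the NLL."""
    n = x_opt.size
    h = np.maximum(np.abs(x_opt) * 1e-4, 1e-8)
    hess = np.empty((n, n))
    f0 = nll(x_opt)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (nll(x_opt + ei) - 2 * f0 + nll(x_opt - ei)) / h[i] ** 2
            else:
                val = (
                    nll(x_opt + ei + ej)
                    - nll(x_opt + ei - ej)
                    - nll(x_opt - ei + ej)
                    + nll(x_opt - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        errs = [math.sqrt(d) if d > 0 else None for d in diag]
    except np.linalg.LinAlgError:
        errs = [None] * n
    return dict(zip(names, errs))


def fit_biexp(hist: DecayHistogram) -> DecayFit:
    """Neyman-weighted least-squares fit of a two-component decay.

    Amplitudes are unconstrained in sign so that forcing a second
    component onto mono-exponential data surfaces as a negative amplitude
    (``physical=False``) rather than being masked by a bound.
    """
    counts = hist.counts
    if hist.total_photons < 1000:
        warnings.warn(
            f"only {hist.total_photons:.0f} photons: fit attempted but "
            "estimates will be noisy",
            stacklevel=2,
        )
    t = hist.bin_centers_ns
    sigma = np.sqrt(np.maximum(counts, 1.0))

    # head/tail split initialisation: the tail is dominated by the slow
    # component, the head excess by the fast one
    split = t.size // 3
    a_tail, tau_tail = _loglinear_init(t[split:], counts[split:])
    head_excess = np.clip(counts[:split] - a_tail * np.exp(-t[:split] / tau_tail), 0, None)
    a_head, tau_head = _loglinear_init(t[:split], head_excess)
    if not (0 < tau_head < tau_tail):
        tau_head = 0.5 * tau_tail

    params = lmfit.Parameters()
    params.add("a1", value=max(a_head, 1e-3))  # sign free
    params.add("tau1", value=tau_head, min=1e-4, max=1e4)
    params.add("a2", value=max(a_tail, 1e-3))
    params.add("tau2", value=tau_tail, min=1e-4, max=1e4)
    params.add("b", value=max(counts.min(), 1e-3), min=0.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        m = (
            p["a1"] * np.exp(-t / p["tau1"])
            + p["a2"] * np.exp(-t / p["tau2"])
            + p["b"]
        )
        return (counts - m) / sigma

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    pairs = sorted(
        [(p["tau1"].value, p["a1"].value, "1"), (p["tau2"].value, p["a2"].value, "2")],
        reverse=True,
    )
    taus = tuple(pr[0] for pr in pairs)
    amps = tuple(pr[1] for pr in pairs)
    amp_sum = sum(amps)
    if abs(amp_sum) < 1e-300:
        fractions = (0.5, 0.5)
    else:
        fractions = tuple(a / amp_sum for a in amps)
    model = amps[0] * np.exp(-t / taus[0]) + amps[1] * np.exp(-t / taus[1]) + p["b"].value
    physical = bool(all(a >= 0 for a in amps) and all(tau > 0 for tau in taus))
    stderr = {
        f"tau_{i + 1}": (p[f"tau{lbl}"].stderr) for i, (_, _, lbl) in enumerate(pairs)
    }
    stderr.update(
        {f"amplitude_{i + 1}": p[f"a{lbl}"].stderr for i, (_, _, lbl) in enumerate(pairs)}
    )
    stderr["background"] = p["b"].stderr
    return DecayFit(
        n_components=2,
        taus=taus,
        fractions=fractions,
        amplitudes=amps,
        background=float(p["b"].value),
        reduced_chisq=_neyman_reduced_chisq(counts, model, 5),
        physical=physical,
        stderr=stderr,
    )


def select_decay_model(
    mono: DecayFit, bi: DecayFit, criterion_threshold: float = 0.05
) -> DecayFit:
    """Choose between mono- and bi-exponential fits of the same histogram.

    The bi-exponential fit wins only if it is physical (no negative
    amplitudes, positive lifetimes) and lowers the Neyman reduced χ² by
    more than ``criterion_threshold``; otherwise the mono fit is returned.
    A fit with a negative amplitude is never selected, however good its χ².
    """
    if mono.n_components != 1 or bi.n_components != 2:
        raise ValueError("expected a mono fit and a bi fit, in that order")
    if bi.physical and (mono.reduced_chisq - bi.reduced_chisq) > criterion_threshold:
        return bi
    return mono
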