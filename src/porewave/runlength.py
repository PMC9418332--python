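"""Nucleation-propagation model of pore-arc run lengths.

Perforin-2 pre-pore rings of ``N = 16`` subunits transition into membrane
pores in single processive runs: a rare nucleation event (probability
``sigma`` per subunit) is followed by clockwise propagation where each next
subunit converts with a probability proportional to the Boltzmann factor
``s = exp(-dE/kT)``.  Long runs are disfavoured by a phenomenological
logistic penalty with characteristic length ``n0``.  This is a ring variant
of the Zimm-Bragg helix-coil treatment.

The statistical weight of a run of length ``n`` (``1 <= n <= N``) is

    w(n) = N * sigma * s**n / (1 + exp(n - n0))

with partition function ``Z = 1 + sum_n w(n)``; ``p(n) = w(n)/Z`` and
``p(0) = 1/Z`` (no run).  The observable arc-length distribution is the
conditional law ``p(n | n >= 1)``, in which ``sigma`` cancels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp


class ParameterError(ValueError):
    """Raised when model parameters are outside their admissible domain."""


@dataclass(frozen=True)
class RunLengthParams:
    """Parameters of the run-length model.

    Parameters
    ----------
    N : int
        Ring size in subunits (16 for perforin-2).
    sigma : float
        Per-subunit nucleation probability, ``0 < sigma < 1``; the regime of
        interest has ``sigma << 1``.
    s : float
        Propagation Boltzmann factor ``exp(-dE/kT)``; ``s > 1`` means the
        pore state is favourable once the neighbour has converted.
    n0 : float or None
        Characteristic length of the long-run penalty.  ``None`` disables
        the penalty (penalty term identically 1).
    """

    N: int = 16
    sigma: float = 0.01
    s: float = 1.0
    n0: float | None = 11.9

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ParameterError(f"N must be an integer >= 1, got {self.N!r}")
        if not (0.0 < self.sigma < 1.0):
            raise ParameterError(f"sigma must be in (0, 1), got {self.sigma!r}")
        if not (self.s > 0.0 and math.isfinite(self.s)):
            raise ParameterError(f"s must be positive and finite, got {self.s!r}")
        if self.n0 is not None and not (self.n0 > 0.0 and math.isfinite(self.n0)):
            raise ParameterError(
                f"n0 must be positive and finite, or None for no penalty; got {self.n0!r}"
            )

    @property
    def penalty_disabled(self) -> bool:
        return self.n0 is None


@dataclass(frozen=True)
class RunLengthPmf:
    """Probabilities of the run-length model: ``p0`` (no run), ``p[n-1]`` for
    runs of ``n = 1..N`` subunits, and the partition function ``Z``."""

    p0: float
    p: np.ndarray
    Z: float

    def conditional(self) -> np.ndarray:
        """``p(n | n >= 1)`` — the observable arc-length law."""
        total = self.p.sum()
        if total <= 0:
            raise ParameterError("conditional pmf undefined: no run mass")
        return self.p / total


@dataclass
class ArcLengthSample:
    """Histogram of observed pore-arc lengths in subunits.

    ``counts[n-1]`` is the number of arcs of length ``n``; ``n_rings_total``
    (optional) is the total number of rings observed, used to estimate the
    nucleation probability from the fraction of rings with a run.
    """

    counts: np.ndarray
    n_rings_total: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or np.any(self.counts < 0):
            raise ValueError("counts must be a 1-D non-negative integer histogram")

    @property
    def n_arcs(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_lengths(
        cls, lengths, N: int = 16, n_rings_total: int | None = None
    ) -> "ArcLengthSample":
        lengths = np.asarray(lengths, dtype=np.int64)
        if lengths.size and (lengths.min() < 1 or lengths.max() > N):
            raise ValueError(f"run lengths must lie in 1..{N}")
        counts = np.bincount(lengths, minlength=N + 1)[1 : N + 1]
        return cls(counts=counts, n_rings_total=n_rings_total)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"run_length": np.arange(1, len(self.counts) + 1), "count": self.counts}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_rings_total: int | None = None) -> "ArcLengthSample":
        df = pd.read_csv(path)
        if not {"run_length", "count"}.issubset(df.columns):
            raise ValueError("arc-length CSV must have columns run_length,count")
        N = int(df["run_length"].max())
        counts = np.zeros(N, dtype=np.int64)
        counts[df["run_length"].to_numpy() - 1] = df["count"].to_numpy()
        return cls(counts=counts, n_rings_total=n_rings_total)


def _log_penalty(n: np.ndarray, n0: float | None) -> np.ndarray:
    """log of the logistic penalty 1/(1 + exp(n - n0)); 0 when disabled."""
    if n0 is None:
        return np.zeros_like(np.asarray(n, dtype=float))
    # -log(1 + e^(n-n0)) computed stably via logaddexp
    return -np.logaddexp(0.0, np.asarray(n, dtype=float) - n0)


def _log_weights(params: RunLengthParams) -> np.ndarray:
    """log w(n) for n = 1..N (run statistical weights, unnormalized)."""
    n = np.arange(1, params.N + 1, dtype=float)
    return (
        math.log(params.N)
        + math.log(params.sigma)
        + n * math.log(params.s)
        + _log_penalty(n, params.n0)
    )


def partition_function(params: RunLengthParams) -> float:
    """Partition function ``Z = 1 + sum_n N sigma s^n / (1 + e^(n-n0))``."""
    return float(1.0 + np.exp(logsumexp(_log_weights(params))))


def run_length_pmf(params: RunLengthParams) -> RunLengthPmf:
    """Full run-length pmf: ``p(0) = 1/Z`` and ``p(n) = w(n)/Z``."""
    logw = _log_weights(params)
    logZ = np.logaddexp(0.0, logsumexp(logw))
    return RunLengthPmf(
        p0=float(np.exp(-logZ)), p=np.exp(logw - logZ), Z=float(np.exp(logZ))
    )


def conditional_pmf(N: int, s: float, n0: float | None) -> np.ndarray:
    """Arc-length law ``p(n | n >= 1)``; independent of sigma by construction."""
    n = np.arange(1, N + 1, dtype=float)
    logw = n * math.log(s) + _log_penalty(n, n0)
    return np.exp(logw - logsumexp(logw))


def coupling_probability_to_s(p_c: float) -> float:
    """Map a per-step coupling probability to the Boltzmann factor via odds.

    ``p_c`` is the probability that the next clockwise subunit converts after
    its neighbour did; the two-state Boltzmann mapping is
    ``s = p_c / (1 - p_c)``, so the reported coupling ~0.64 corresponds to
    ``s ~ 1.78 > 1`` (favourable propagation).
    """
    if not (0.0 < p_c < 1.0):
        raise ParameterError(f"coupling probability must be in (0, 1), got {p_c!r}")
    return p_c / (1.0 - p_c)


def s_to_coupling(s: float) -> float:
    """Inverse of :func:`coupling_probability_to_s`: ``p_c = s / (1 + s)``."""
    if not (s > 0.0 and math.isfinite(s)):
        raise ParameterError(f"s must be positive and finite, got {s!r}")
    return s / (1.0 + s)


def pmf_mode(params: RunLengthParams) -> int:
    """argmax over ``n in 1..N`` of ``p(n)``; ties break toward smaller n."""
    logw = _log_weights(params)
    return int(np.argmax(logw)) + 1  # argmax returns the first maximum


def sample_run_lengths(
    params: RunLengthParams, n_samples: int, seed=None
) -> ArcLengthSample:
    """Draw i.i.d. run lengths from ``p(n | n >= 1)`` (a run occurred)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    pcond = conditional_pmf(params.N, params.s, params.n0)
    lengths = rng.choice(np.arange(1, params.N + 1), size=n_samples, p=pcond)
    return ArcLengthSample.from_lengths(lengths, N=params.N)


@dataclass
class RunLengthFit:
    """Maximum-likelihood fit of the run-length model to an arc sample."""

    params: RunLengthParams
    log_likelihood: float
    converged: bool
    sigma_estimated: bool
    n_arcs: int
    continuous_argmax: float = field(default=float("nan"))

    def to_json(self, path=None) -> str:
        d = {
            "N": self.params.N,
            "s": self.params.s,
            "coupling_probability": s_to_coupling(self.params.s),
            "n0": self.params.n0,
            "sigma": self.params.sigma if self.sigma_estimated else None,
            "sigma_estimated": self.sigma_estimated,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_arcs": self.n_arcs,
            "mode": pmf_mode(self.params),
            "continuous_argmax": self.continuous_argmax,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _continuous_argmax(s: float, n0: float) -> float:
    """Argmax over real n of s^n / (1 + e^(n-n0)) on [1, inf).

    Distinct from the discrete mode and from n0 itself; exposed so the two
    quantities are never conflated.
    """
    from scipy.optimize import minimize_scalar

    def neg(n):
        return -(n * math.log(s) - np.logaddexp(0.0, n - n0))

    res = minimize_scalar(neg, bounds=(1.0, n0 + 30.0), method="bounded")
    return float(res.x)


def fit_run_lengths(sample: ArcLengthSample, N: int = 16) -> RunLengthFit:
    """Fit ``(s, n0)`` by maximum likelihood on the conditional pmf.

    sigma cancels in ``p(n | n >= 1)`` and is estimated separately from the
    fraction of rings with a run when ``sample.n_rings_total`` is provided;
    otherwise it is reported as undetermined (a nominal placeholder value is
    stored but flagged).
    """
    counts = np.zeros(N, dtype=np.int64)
    k = min(N, len(sample.counts))
    counts[:k] = sample.counts[:k]
    if counts.sum() == 0:
        raise ValueError("cannot fit an empty arc-length sample")
    if np.count_nonzero(counts) < 2:
        raise ValueError(
            "degenerate sample: all mass on a single run length; (s, n0) unidentifiable"
        )

    n = np.arange(1, N + 1, dtype=float)

    def nll(x):
        log_s, log_n0 = x
        logw = n * log_s + _log_penalty(n, math.exp(log_n0))
        return -(counts * (logw - logsumexp(logw))).sum()

    best = None
    for x0 in ((0.5, math.log(12.0)), (0.0, math.log(8.0)), (1.0, math.log(15.0))):
        res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    s_hat = math.exp(best.x[0])
    n0_hat = math.exp(best.x[1])

    sigma_hat, sigma_estimated = 0.01, False
    if sample.n_rings_total:
        f = sample.n_arcs / sample.n_rings_total
        if 0.0 < f < 1.0:
            # 1 - 1/Z = f  =>  sum_n w(n) = f/(1-f), solve for sigma
            logw_unit = n * math.log(s_hat) + _log_penalty(n, n0_hat) + math.log(N)
            denom = float(np.exp(logsumexp(logw_unit)))
            cand = (f / (1.0 - f)) / denom
            if 0.0 < cand < 1.0:
                sigma_hat, sigma_estimated = cand, True

    params = RunLengthParams(N=N, sigma=sigma_hat, s=s_hat, n0=n0_hat)
    return RunLengthFit(
        params=params,
        log_likelihood=-best.fun,
        converged=bool(best.success),
        sigma_estimated=sigma_estimated,
        n_arcs=int(counts.sum()),
        continuous_argmax=_continuous_argmax(s_hat, n0_hat),
    )
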