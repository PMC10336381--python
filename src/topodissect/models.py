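"""Amino-acid substitution models.

Time-reversible 20-state models in the GTR family: a symmetric matrix of
exchangeabilities s_ij and stationary frequencies pi give the generator
Q_ij = s_ij * pi_j (i != j), with the diagonal set so rows sum to zero and
the whole matrix rescaled so that -sum_i pi_i Q_ii = 1, i.e. branch lengths
are in expected substitutions per site.  Among-site rate variation uses the
discrete-gamma approximation with equal-weight categories represented by
their category means.

Empirical matrices (LG, WAG, JTT) are shipped as PAML-format data files;
``poisson_model`` builds the equal-rates, equal-frequency chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.special import gammaincinv, gammainc

N_STATES = 20


@dataclass(frozen=True)
class SubstitutionModel:
    """Exchangeabilities + frequencies + optional discrete-gamma rates."""

    name: str
    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,) positive, sums to 1
    gamma_shape: float | None = None
    n_rate_categories: int = 1

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(s < 0):
            raise ValueError("negative exchangeability")
        if f.shape != (N_STATES,):
            raise ValueError("frequencies must be length 20")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be > 0")
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", f / f.sum())
        if self.gamma_shape is not None:
            if self.gamma_shape <= 0:
                raise ValueError("gamma shape must be positive")
            if self.n_rate_categories < 2:
                object.__setattr__(self, "n_rate_categories", 4)

    @property
    def n_free_parameters(self) -> int:
        """Parameters estimated per locus (empirical matrices are fixed)."""
        return 0 if self.gamma_shape is None else 1

    def with_gamma(self, shape: float, k: int = 4) -> "SubstitutionModel":
        return replace(
            self,
            name=f"{self.name.split('+')[0]}+G{k}",
            gamma_shape=shape,
            n_rate_categories=k,
        )

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Equal-weight discrete gamma category rates (category means).

    The mean-one gamma(shape, shape) density is cut at its k-quantiles and
    each category is represented by its conditional mean, so the rates
    average exactly to 1.
    """
    a = float(shape)
    # quantile boundaries of gamma(a, rate=a); scale cancels in the ratio
    bounds = gammaincinv(a, np.arange(1, k) / k) / a
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X | lower < X <= upper] * (1/k)^-1 via the incomplete-gamma identity
    cdf_hi = gammainc(a + 1, np.where(np.isinf(upper), np.inf, upper * a))
    cdf_hi = np.where(np.isinf(upper), 1.0, cdf_hi)
    cdf_lo = gammainc(a + 1, lower * a)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalized generator: Q_ij = s_ij pi_j, rows sum to 0, rate 1."""
    pi = model.frequencies
    if np.any(pi <= 0):
        raise ValueError("zero frequency")
    Q = model.exchangeabilities * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
    rate = -np.sum(pi * np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate model: zero total rate")
    return Q / rate


class TransitionKernel:
    """Eigendecomposition-backed transition probabilities P(t).

    The generator is similarity-transformed to the symmetric
    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) and diagonalized once; each P(t)
    is then two small matrix products, numerically stable for any t >= 0.
    """

    def __init__(self, model: SubstitutionModel):
        self.model = model
        self.pi = model.frequencies
        self.Q = build_rate_matrix(model)
        sq = np.sqrt(self.pi)
        B = (self.Q / sq[None, :]) * sq[:, None]
        B = 0.5 * (B + B.T)  # symmetrize against rounding
        lam, U = np.linalg.eigh(B)
        self._lam = np.minimum(lam, 0.0)  # generator spectrum is non-positive
        self._left = U / sq[:, None]  # diag(1/sqrt(pi)) U
        self._right = U.T * sq[None, :]  # U^T diag(sqrt(pi))

    def probs(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t * rate); rows sum to 1."""
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        w = np.exp(self._lam * (t * rate))
        P = (self._left * w[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


def transition_probs(
    model: SubstitutionModel, t: float, rate: float = 1.0
) -> np.ndarray:
    return TransitionKernel(model).probs(t, rate)


# ------------------------------------------------------------------ loading

_EMPIRICAL_FILES = {"LG": "lg.dat", "WAG": "wag.dat", "JTT": "jtt.dat"}


def _parse_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = [ln.split() for ln in text.strip().splitlines() if ln.strip()]
    vals = [float(x) for row in rows[:19] for x in row]
    if len(vals) != 190:
        raise ValueError("expected 190 lower-triangle exchangeabilities")
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    freqs = np.array([float(x) for x in rows[19]])
    if freqs.shape != (N_STATES,):
        raise ValueError("expected 20 frequencies")
    return S, freqs


def empirical_model(name: str) -> SubstitutionModel:
    """Load LG, WAG or JTT with the matrix's own frequencies."""
    key = name.upper()
    if key not in _EMPIRICAL_FILES:
        raise KeyError(f"unknown empirical model {name!r}")
    text = (
        resources.files("topodissect.data")
        .joinpath(_EMPIRICAL_FILES[key])
        .read_text()
    )
    S, f = _parse_paml_dat(text)
    return SubstitutionModel(key, S, f)


def poisson_model() -> SubstitutionModel:
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel("POISSON", S, np.full(N_STATES, 1 / N_STATES))


def get_model(
    spec: str, observed_frequencies: np.ndarray | None = None
) -> SubstitutionModel:
    """Resolve a model name like 'LG', 'LG+G4', 'POISSON+G4' or 'WAG+F+G4'.

    '+F' replaces the matrix frequencies with ``observed_frequencies``.
    """
    parts = spec.upper().split("+")
    base = parts[0]
    model = poisson_model() if base == "POISSON" else empirical_model(base)
    for p in parts[1:]:
        if p == "F":
            if observed_frequencies is None:
                raise ValueError("'+F' requires observed frequencies")
            model = replace(model, name=model.name + "+F",
                            frequencies=np.asarray(observed_frequencies))
        elif p.startswith("G"):
            k = int(p[1:]) if len(p) > 1 else 4
            model = model.with_gamma(shape=1.0, k=k)
        else:
            raise ValueError(f"unknown model component {p!r} in {spec!r}")
    return model
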