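"""Substitution models and rate heterogeneity.

The general time-reversible (GTR) rate matrix is Q_ij = s_ij * pi_j for
i != j, with symmetric exchangeabilities s and stationary frequencies pi,
normalised so the expected number of substitutions per unit branch length
is one.  Transition probabilities come from the eigendecomposition of the
similar symmetric matrix diag(sqrt(pi)) Q diag(1/sqrt(pi)), so eigenvalues
are real and P(t) = U exp(L t) U^-1 is numerically stable.

For DNA, the six exchangeability slots (AC, AG, AT, CG, CT, GT) may be
linked: any set partition of the slots shares one free rate per class,
which generates every time-reversible DNA sub-model (203 = Bell(6) in
total, including JC/F81 and K80/HKY as the one- and two-class cases).
Among-site rate heterogeneity is either the discrete-Gamma model (c
mean-of-category rates from Gamma(alpha, alpha), equal weights) or the
per-site-rate (PSR) model, which hard-assigns each site to one of c freely
estimated rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .aa_data import AA_MODEL_DATA, SYNTHETIC_MODELS
from .model_tokens import AA_MODEL_NAMES, ModelSpec, is_linkage_string, parse_model_token
from .states import AA, BINARY, DNA, DataTypeInfo, get_type

DNA_SLOTS = ("AC", "AG", "AT", "CG", "CT", "GT")
FREQ_FLOOR = 1e-6


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTR rate linkage: set partitions of the six exchangeability slots

def set_partitions(n: int) -> list[str]:
    """All set partitions of n items as restricted-growth strings,
    lexicographically ordered."""
    out: list[str] = []

    def rec(prefix: list[int], top: int) -> None:
        if len(prefix) == n:
            out.append("".join(map(str, prefix)))
            return
        for d in range(top + 2):
            prefix.append(d)
            rec(prefix, max(top, d))
            prefix.pop()

    rec([0], 0) if n else out.append("")
    return out


@dataclass(frozen=True)
class RateLinkage:
    """A set partition of the six DNA exchangeability slots.

    ``rgs`` is the restricted-growth string (e.g. ``"010010"`` links the
    two transitions AG and CT).  The class containing the GT slot is the
    reference class, pinned to rate 1.
    """

    rgs: str

    def __post_init__(self) -> None:
        if not is_linkage_string(self.rgs):
            raise ModelError(f"not a restricted-growth string over 6 slots: {self.rgs!r}")

    @property
    def n_classes(self) -> int:
        return max(int(c) for c in self.rgs) + 1

    @property
    def class_of_slot(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.rgs)

    @property
    def reference_class(self) -> int:
        return int(self.rgs[5])  # class of the GT slot

    @property
    def free_classes(self) -> tuple[int, ...]:
        ref = self.reference_class
        return tuple(k for k in range(self.n_classes) if k != ref)

    def classes(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_classes)]
        for slot, k in zip(DNA_SLOTS, self.class_of_slot):
            out[k].append(slot)
        return out

    def expand(self, class_rates: np.ndarray) -> np.ndarray:
        """Per-slot exchangeabilities from per-class rates (reference = 1)."""
        rates = np.asarray(class_rates, dtype=float).copy()
        rates[self.reference_class] = 1.0
        return rates[np.array(self.class_of_slot)]


def enumerate_gtr_linkages() -> list[RateLinkage]:
    """All 203 time-reversible DNA rate-linkage schemes (Bell(6))."""
    return [RateLinkage(r) for r in set_partitions(6)]


# ---------------------------------------------------------------------------
# Substitution model with eigendecomposition

def _exch_vector_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Lower-triangle column-major exchangeabilities -> symmetric matrix."""
    m = np.zeros((n, n))
    k = 0
    for j in range(n):
        for i in range(j + 1, n):
            m[i, j] = m[j, i] = vec[k]
            k += 1
    if k != len(vec):
        raise ModelError(f"expected {k} exchangeabilities, got {len(vec)}")
    return m


class SubstitutionModel:
    """Reversible rate matrix with cached eigendecomposition.

    Mutating ``set_frequencies`` / ``set_class_rates`` rebuilds Q and the
    eigen system; any cached transition matrices must then be discarded by
    the caller (the likelihood engine versions models for this purpose).
    """

    def __init__(self, n_states: int, exch: np.ndarray, freqs: np.ndarray,
                 linkage: RateLinkage | None = None,
                 class_rates: np.ndarray | None = None,
                 name: str = "custom"):
        self.n_states = n_states
        self.name = name
        self.linkage = linkage
        self._class_rates = (np.asarray(class_rates, float)
                             if class_rates is not None else None)
        self.exch = np.asarray(exch, float)
        self.freqs = self._check_freqs(freqs)
        self.version = 0
        self._rebuild()

    # -- constructors -------------------------------------------------------

    @classmethod
    def dna(cls, linkage: str | RateLinkage = "012345",
            class_rates: np.ndarray | None = None,
            freqs: np.ndarray | None = None) -> "SubstitutionModel":
        link = linkage if isinstance(linkage, RateLinkage) else RateLinkage(linkage)
        if class_rates is None:
            class_rates = np.ones(link.n_classes)
        class_rates = np.asarray(class_rates, float)
        if class_rates.shape != (link.n_classes,):
            raise ModelError(f"linkage {link.rgs} needs {link.n_classes} class rates")
        if freqs is None:
            freqs = np.full(4, 0.25)
        exch = _exch_vector_to_matrix(link.expand(class_rates), 4)
        return cls(4, exch, freqs, linkage=link, class_rates=class_rates,
                   name=f"DNA[{link.rgs}]")

    @classmethod
    def empirical_aa(cls, name: str, freqs: np.ndarray | None = None) -> "SubstitutionModel":
        key = name.upper()
        if key not in AA_MODEL_DATA:
            raise ModelError(
                f"unknown amino-acid model {name!r}; available: "
                + ", ".join(sorted(AA_MODEL_DATA)))
        vec, model_freqs = AA_MODEL_DATA[key]
        if freqs is None:
            freqs = np.asarray(model_freqs, float)
            freqs = freqs / freqs.sum()
        exch = _exch_vector_to_matrix(np.asarray(vec, float), 20)
        return cls(20, exch, freqs, name=key)

    @classmethod
    def binary(cls, freqs: np.ndarray | None = None) -> "SubstitutionModel":
        if freqs is None:
            freqs = np.full(2, 0.5)
        return cls(2, np.array([[0.0, 1.0], [1.0, 0.0]]), freqs, name="BIN")

    @property
    def is_synthetic(self) -> bool:
        return self.name in SYNTHETIC_MODELS

    # -- mutation -----------------------------------------------------------

    def set_frequencies(self, freqs: np.ndarray) -> None:
        self.freqs = self._check_freqs(freqs)
        self._rebuild()

    @property
    def class_rates(self) -> np.ndarray:
        if self._class_rates is None:
            raise ModelError("model has no rate linkage")
        return self._class_rates.copy()

    def set_class_rates(self, class_rates: np.ndarray) -> None:
        if self.linkage is None:
            raise ModelError("model has no rate linkage")
        rates = np.asarray(class_rates, float).copy()
        if np.any(rates <= 0):
            raise ModelError("class rates must be positive")
        rates[self.linkage.reference_class] = 1.0
        self._class_rates = rates
        self.exch = _exch_vector_to_matrix(self.linkage.expand(rates), 4)
        self._rebuild()

    # -- internals ----------------------------------------------------------

    def _check_freqs(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, float)
        if f.shape != (self.n_states,):
            raise ModelError(f"need {self.n_states} frequencies")
        if np.any(f <= 0):
            raise ModelError("state frequencies must be strictly positive")
        return f / f.sum()

    def _rebuild(self) -> None:
        pi = self.freqs
        s = self.exch
        if not np.any(s > 0):
            raise ModelError("all exchangeabilities are zero")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))
        q /= scale
        self.Q = q
        # symmetrise: B = D Q D^-1 with D = diag(sqrt(pi)) is symmetric
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        lam, v = np.linalg.eigh((b + b.T) / 2)
        self.eigenvalues = lam
        self.U = v / sq[:, None]
        self.Uinv = v.T * sq[None, :]
        self.version += 1

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) = U exp(L rate t) U^-1, clamped to [0, 1]."""
        if t < 0:
            raise ModelError("branch length must be >= 0")
        e = np.exp(self.eigenvalues * (rate * t))
        p = (self.U * e[None, :]) @ self.Uinv
        return np.clip(p, 0.0, 1.0)

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """(n_categories, n, n) stack of P(r_j * t)."""
        e = np.exp(np.multiply.outer(np.asarray(rates, float) * t, self.eigenvalues))
        p = np.einsum("ik,jk,kl->jil", self.U, e, self.Uinv, optimize=True)
        return np.clip(p, 0.0, 1.0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubstitutionModel({self.name}, {self.n_states} states)"


# ---------------------------------------------------------------------------
# Rate heterogeneity

def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-of-category discretization of Gamma(alpha, alpha) into
    ``n_categories`` equiprobable categories; exact unit mean."""
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    c = int(n_categories)
    if c < 1:
        raise ModelError("need at least one rate category")
    if c == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, c) / c, a=alpha, scale=1.0 / alpha)
    # integral of x * pdf over a category, via the shape+1 incomplete gamma
    upper_cdf = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    upper_cdf = np.concatenate([[0.0], upper_cdf, [1.0]])
    rates = np.diff(upper_cdf) * c
    rates /= rates.mean()  # exact unit mean
    if np.any(np.diff(rates) <= 0):
        raise ModelError("gamma discretization produced non-increasing rates")
    return rates


@dataclass
class RateHeterogeneity:
    """Among-site rate model: NONE, discrete GAMMA, or PSR."""

    mode: str = "NONE"                      # NONE | GAMMA | PSR
    n_categories: int = 1
    alpha: float = 1.0                      # GAMMA only
    psr_rates: np.ndarray | None = None     # PSR only

    def __post_init__(self) -> None:
        if self.mode not in ("NONE", "GAMMA", "PSR"):
            raise ModelError(f"unknown rate-heterogeneity mode {self.mode!r}")
        if self.mode == "NONE":
            self.n_categories = 1
        if self.mode == "PSR" and self.psr_rates is None:
            # evenly spread starting rates, unit mean
            c = self.n_categories
            self.psr_rates = np.linspace(0.5, 1.5, c)
            self.psr_rates /= self.psr_rates.mean()

    def rates(self) -> np.ndarray:
        if self.mode == "GAMMA":
            return discrete_gamma_rates(self.alpha, self.n_categories)
        if self.mode == "PSR":
            return np.asarray(self.psr_rates, float)
        return np.ones(1)

    def set_alpha(self, alpha: float) -> None:
        if self.mode != "GAMMA":
            raise ModelError("alpha applies to the GAMMA model only")
        self.alpha = float(alpha)


# ---------------------------------------------------------------------------
# Empirical frequencies

def empirical_frequencies(patterns: list[str], weights: np.ndarray,
                          taxon_count: int, dt: DataTypeInfo) -> np.ndarray:
    """Weighted state counts normalised to the simplex.

    Partially ambiguous codes distribute their mass equally over the
    compatible states; gaps and fully unknown codes carry no information
    and are skipped.  Zero frequencies are floored at 1e-6 and the vector
    renormalised.
    """
    counts = np.zeros(dt.n_states)
    for col, w in zip(patterns, weights):
        for ch in col:
            compat = dt.codes[ch]
            if len(compat) == dt.n_states:
                continue
            share = w / len(compat)
            for s in compat:
                counts[dt.state_index[s]] += share
    total = counts.sum()
    if total <= 0:
        raise ModelError("cannot estimate frequencies: partition entirely missing")
    freqs = counts / total
    freqs = np.maximum(freqs, FREQ_FLOOR)
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Partition model: substitution model + heterogeneity + flags

@dataclass
class PartitionModel:
    """Everything needed to evaluate one partition's likelihood."""

    spec: ModelSpec
    dtype: DataTypeInfo
    subst: SubstitutionModel
    het: RateHeterogeneity
    ascertainment: bool = False
    freq_mode: str = "empirical"

    @classmethod
    def from_spec(cls, token_or_spec: str | ModelSpec,
                  patterns: list[str] | None = None,
                  weights: np.ndarray | None = None,
                  n_taxa: int = 0) -> "PartitionModel":
        spec = (token_or_spec if isinstance(token_or_spec, ModelSpec)
                else parse_model_token(token_or_spec))
        dt = get_type(spec.data_type)
        freqs = None
        if spec.freq_mode in ("empirical", "ml") and patterns is not None:
            freqs = empirical_frequencies(patterns, weights, n_taxa, dt)
        if spec.data_type == DNA:
            subst = SubstitutionModel.dna(spec.linkage, freqs=freqs)
        elif spec.data_type == AA:
            subst = SubstitutionModel.empirical_aa(
                spec.base, freqs=freqs if spec.freq_mode != "model" else None)
        else:
            subst = SubstitutionModel.binary(freqs=freqs)
        if spec.gamma:
            het = RateHeterogeneity("GAMMA", spec.gamma_categories, alpha=1.0)
        elif spec.psr:
            het = RateHeterogeneity("PSR", spec.psr_categories)
        else:
            het = RateHeterogeneity("NONE")
        return cls(spec, dt, subst, het, ascertainment=spec.ascertainment,
                   freq_mode=spec.freq_mode)

    def category_rates(self) -> np.ndarray:
        return self.het.rates()

    def category_weights(self) -> np.ndarray:
        c = self.het.n_categories if self.het.mode != "NONE" else 1
        return np.full(c, 1.0 / c)


def empirical_aa_model_names() -> tuple[str, ...]:
    """The 18-model empirical amino-acid catalog."""
    return AA_MODEL_NAMES
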