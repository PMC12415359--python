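"""Additive and dominance genotype codings under Hardy-Weinberg equilibrium.

A biallelic marker with B-allele frequency ``p`` has HWE genotype-class
probabilities ``(1-p)^2, 2p(1-p), p^2`` for the B-allele counts 0, 1, 2.
The additive coding is the allele count itself; the dominance codings
quantify the heterozygote's deviation in different ways:

==========  ==================  =============================================
name        codes (AA, AB, BB)  interpretation
==========  ==================  =============================================
additive    0, 1, 2             allele count (breeding-value axis)
het         0, 1, 0             extra effect of the heterozygote
carrier     0, 1, 1             carrier status of the B allele
orthogonal  0, 2p, 4p-2         dominance deviation; orthogonal to additive
half        -1/2, 1/2, -1/2     centred heterozygote contrast (alias of het)
third       -1/3, 2/3, -1/3     centred heterozygote contrast (alias of het)
==========  ==================  =============================================

The ``half`` and ``third`` codings are affine shifts of ``het``, so after
column standardization they produce identical matrices and identical GRMs;
they are resolved to ``het`` before standardization so the equality is exact
to the last bit, and the alias is recorded on the result.

Each scheme carries closed-form HWE moments.  ``standardize`` always uses
these theoretical moments at the supplied allele frequencies (not empirical
column moments), matching the usual GRM construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "EncodingScheme",
    "StandardizedMatrix",
    "get_scheme",
    "scheme_names",
    "encode",
    "theoretical_moments",
    "standardize",
    "encoding_covariance",
    "hwe_weights",
]

_VAR_FLOOR = 1e-12


def hwe_weights(p):
    """HWE genotype-class probabilities for B-counts (0, 1, 2) at frequency p."""
    p = np.asarray(p, dtype=float)
    return np.stack([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])


@dataclass(frozen=True)
class EncodingScheme:
    """A genotype coding with its closed-form HWE mean and variance.

    ``values_fn(p)`` returns the coded values for B-counts (0, 1, 2); shape
    ``(3,)`` for a scalar p or ``(3, len(p))`` for a vector of frequencies.
    ``alias_of`` names the canonical scheme this one standardizes to.
    """

    name: str
    values_fn: Callable[[np.ndarray], np.ndarray]
    mean_fn: Callable[[np.ndarray], np.ndarray]
    var_fn: Callable[[np.ndarray], np.ndarray]
    is_dominance: bool = True
    alias_of: str | None = None

    def genotype_values(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.values_fn(p)

    def mean(self, p):
        return self.mean_fn(np.asarray(p, dtype=float))

    def var(self, p):
        return self.var_fn(np.asarray(p, dtype=float))

    @property
    def canonical(self) -> "EncodingScheme":
        return self if self.alias_of is None else get_scheme(self.alias_of)


def _const(values):
    v = np.asarray(values, dtype=float)

    def fn(p):
        if np.ndim(p) == 0:
            return v.copy()
        return np.broadcast_to(v[:, None], (3,) + np.shape(p)).copy()

    return fn


def _het_var(p):
    h = 2.0 * p * (1.0 - p)
    return h * (1.0 - h)


_SCHEMES: dict[str, EncodingScheme] = {}


def _register(s: EncodingScheme):
    _SCHEMES[s.name] = s
    return s


_register(
    EncodingScheme(
        "additive",
        _const([0.0, 1.0, 2.0]),
        lambda p: 2.0 * p,
        lambda p: 2.0 * p * (1.0 - p),
        is_dominance=False,
    )
)
_register(
    EncodingScheme(
        "het",
        _const([0.0, 1.0, 0.0]),
        lambda p: 2.0 * p * (1.0 - p),
        _het_var,
    )
)
_register(
    EncodingScheme(
        "carrier",
        _const([0.0, 1.0, 1.0]),
        lambda p: p**2 + 2.0 * p * (1.0 - p),
        lambda p: (1.0 - p) ** 2 - (1.0 - p) ** 4,
    )
)
_register(
    EncodingScheme(
        "orthogonal",
        lambda p: np.stack(
            [np.zeros_like(p), 2.0 * p, 4.0 * p - 2.0]
        ),
        lambda p: 2.0 * p**2,
        lambda p: 4.0 * p**2 * (1.0 - p) ** 2,
    )
)
_register(
    EncodingScheme(
        "half",
        _const([-0.5, 0.5, -0.5]),
        lambda p: 2.0 * p * (1.0 - p) - 0.5,
        _het_var,
        alias_of="het",
    )
)
_register(
    EncodingScheme(
        "third",
        _const([-1.0 / 3.0, 2.0 / 3.0, -1.0 / 3.0]),
        lambda p: 2.0 * p * (1.0 - p) - 1.0 / 3.0,
        _het_var,
        alias_of="het",
    )
)


def scheme_names() -> list[str]:
    return list(_SCHEMES)


def get_scheme(name) -> EncodingScheme:
    if isinstance(name, EncodingScheme):
        return name
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown encoding scheme {name!r}; choose from {sorted(_SCHEMES)}"
        ) from None


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column-standardized coded genotypes: (Z - E[Z]) / sqrt(var[Z]) at p.

    ``encoding`` is the canonical scheme name actually used; ``alias`` keeps
    the requested name when it resolved to another scheme.
    """

    values: np.ndarray
    encoding: str
    frequencies: np.ndarray
    alias: str | None = None

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


def _check_p(p, allow_vector=True):
    p = np.asarray(p, dtype=float)
    if not allow_vector and p.ndim != 0:
        raise ValueError("p must be a scalar")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("allele frequency p must lie strictly in (0, 1)")
    return p


def encode(genotypes, scheme, p=None) -> np.ndarray:
    """Apply a coding elementwise to a B-allele-count matrix.

    Parameters
    ----------
    genotypes : (n, m) array with values in {0, 1, 2}
    scheme : EncodingScheme or name
    p : per-marker B-allele frequency, required for frequency-dependent
        schemes (``orthogonal``).
    """
    scheme = get_scheme(scheme)
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[:, None]
    gi = g.astype(np.int64, copy=False)
    if np.any(gi != g) or gi.min(initial=0) < 0 or gi.max(initial=0) > 2:
        raise ValueError("genotypes must be integers in {0, 1, 2}")
    if scheme.name != "orthogonal":
        # frequency-independent codes: p (if supplied) is irrelevant
        return scheme.genotype_values(0.5)[gi]
    if p is None:
        raise ValueError("the orthogonal scheme needs per-marker frequencies p")
    p = _check_p(np.broadcast_to(np.asarray(p, float), (g.shape[1],)))
    vals = scheme.genotype_values(p)  # (3, m)
    return vals[gi, np.arange(g.shape[1])[None, :]]


def theoretical_moments(scheme, p):
    """Closed-form HWE (mean, variance) of the coded marker at frequency p."""
    scheme = get_scheme(scheme)
    p = _check_p(p)
    return scheme.mean(p), scheme.var(p)


def standardize(raw, p, scheme) -> StandardizedMatrix:
    """Standardize coded columns by theoretical HWE moments at the given p.

    Alias schemes (``half``, ``third``) are first shifted onto the ``het``
    codes (an exact affine translation) so the standardized matrix is
    bit-identical to the het one.
    """
    scheme = get_scheme(scheme)
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    m = raw.shape[1]
    p = _check_p(np.broadcast_to(np.asarray(p, float), (m,)).copy())
    alias = None
    if scheme.alias_of is not None:
        # het codes = alias codes + offset (offset = -code(AA)); exact in fp
        offset = -scheme.genotype_values(0.5)[0]
        raw = raw + offset
        alias, scheme = scheme.name, scheme.canonical
    mu = scheme.mean(p)
    var = scheme.var(p)
    bad = ~(var > _VAR_FLOOR)
    if np.any(bad):
        idx = np.flatnonzero(bad)
        raise ValueError(
            f"degenerate theoretical variance for marker column(s) {idx.tolist()}; "
            "remove monomorphic/near-fixed markers before standardizing"
        )
    M = (raw - mu[None, :]) / np.sqrt(var)[None, :]
    return StandardizedMatrix(M, scheme.name, p, alias=alias)


def encoding_covariance(scheme, p) -> float:
    """HWE covariance between the additive coding and a dominance coding.

    Probability-weighted enumeration over the three genotype classes; for the
    closed forms this reproduces: 2p(1-p)(1-2p) for het, 2p(1-p)^2 for
    carrier, and identically 0 for the orthogonal coding.
    """
    scheme = get_scheme(scheme)
    p = _check_p(p)
    w = hwe_weights(p)
    za = get_scheme("additive").genotype_values(p)
    zd = scheme.genotype_values(p)
    e_ad = np.sum(w * za * zd, axis=0)
    return e_ad - np.sum(w * za, axis=0) * np.sum(w * zd, axis=0)
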