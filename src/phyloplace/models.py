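"""Substitution models for placement likelihoods.

Supports the general time-reversible (GTR) nucleotide model and the LG and
WAG empirical amino-acid replacement models, each combined with discrete-Γ
rate heterogeneity across sites.  Model parameters are *inputs*: they are
read from a flat key-value model file or imported (best effort) from
PHYML/RAxML statistics output; no parameter estimation happens here.

The instantaneous rate matrix is built as ``Q_ij = s_ij * pi_j`` for
``i != j`` from a symmetric exchangeability matrix ``s`` and stationary
frequencies ``pi``, with the diagonal set so rows sum to zero and the whole
matrix rescaled so the expected substitution rate at stationarity is one.
Branch lengths are therefore in expected substitutions per site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from ._empirical import AA_ORDER, LG_EXCH_UPPER, LG_FREQS, WAG_EXCH_UPPER, WAG_FREQS

NT_ORDER = "ACGT"

__all__ = [
    "SubstModel",
    "RateCategories",
    "build_rate_matrix",
    "discrete_gamma",
    "transition_matrix",
    "gtr",
    "jc69",
    "lg",
    "wag",
    "read_model_file",
    "write_model_file",
    "import_phyml_stats",
    "import_raxml_info",
    "NT_ORDER",
    "AA_ORDER",
]


@dataclass
class RateCategories:
    """Discrete-Γ rate categories: equal-probability classes with unit mean."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)


def discrete_gamma(alpha: float, ncat: int, median: bool = False) -> RateCategories:
    """Discretize Γ(α, α) into ``ncat`` equal-probability rate categories.

    Each category's representative rate is the mean of its quantile slice
    (Yang 1994); ``median=True`` uses the slice median instead.  The rates
    are rescaled to mean exactly one.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if ncat < 1:
        raise ValueError(f"need at least one rate category, got {ncat}")
    if ncat == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    dist = _gamma_dist(a=alpha, scale=1.0 / alpha)
    probs = np.arange(1, ncat) / ncat
    cuts = dist.ppf(probs)
    if median:
        mids = dist.ppf((np.arange(ncat) + 0.5) / ncat)
        rates = mids / np.mean(mids)
    else:
        # mean of a Gamma(a, scale) slice: scale*a/prob * [F_{a+1}(hi) - F_{a+1}(lo)]
        upper = _gamma_dist(a=alpha + 1, scale=1.0 / alpha)
        cdf_hi = np.append(upper.cdf(cuts), 1.0)
        cdf_lo = np.insert(upper.cdf(cuts), 0, 0.0)
        rates = ncat * (cdf_hi - cdf_lo)
        rates /= rates.mean()
    weights = np.full(ncat, 1.0 / ncat)
    return RateCategories(rates, weights)


def build_rate_matrix(exchangeabilities: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Build the normalized reversible rate matrix Q.

    ``Q_ij = s_ij pi_j`` off-diagonal, rows summing to zero, scaled so the
    expected rate ``-sum_i pi_i Q_ii`` equals one.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if s.shape[0] != s.shape[1] or s.shape[0] != pi.shape[0]:
        raise ValueError("exchangeability matrix and frequency vector sizes differ")
    if not np.allclose(s, s.T, rtol=0, atol=1e-10):
        raise ValueError("exchangeability matrix must be symmetric")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("stationary frequencies must be positive and sum to 1")
    pi = pi / pi.sum()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.dot(pi, np.diag(q))
    return q / rate


@dataclass
class SubstModel:
    """A reversible substitution model with discrete-Γ rate heterogeneity.

    Transition probabilities are computed through the symmetric
    eigendecomposition of ``diag(pi)^(1/2) Q diag(pi)^(-1/2)``, which is
    numerically stable for reversible Q and is cached on first use.
    """

    exchangeabilities: np.ndarray
    stationary_freqs: np.ndarray
    gamma_shape: float = 1.0
    n_rate_cats: int = 4
    name: str = "GTR"
    gamma_median: bool = False
    _eig: tuple = field(default=None, repr=False, compare=False)
    _rc: RateCategories = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.stationary_freqs = np.asarray(self.stationary_freqs, dtype=float)
        self.stationary_freqs = self.stationary_freqs / self.stationary_freqs.sum()

    @property
    def alphabet_size(self) -> int:
        return len(self.stationary_freqs)

    @property
    def alphabet(self) -> str:
        return NT_ORDER if self.alphabet_size == 4 else AA_ORDER

    @property
    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.exchangeabilities, self.stationary_freqs)

    @property
    def rate_categories(self) -> RateCategories:
        if self._rc is None:
            self._rc = discrete_gamma(self.gamma_shape, self.n_rate_cats, self.gamma_median)
        return self._rc

    def _eigen(self):
        if self._eig is None:
            q = self.rate_matrix
            pi = self.stationary_freqs
            sq = np.sqrt(pi)
            sym = (q * sq[:, None]) / sq[None, :]
            lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
            right = u / sq[:, None]          # columns: right eigenvectors of Q
            left = u.T * sq[None, :]         # rows: left eigenvectors
            self._eig = (lam, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for a single branch length ``t`` (no rate mixing)."""
        if t < 0:
            raise ValueError(f"branch length must be nonnegative, got {t}")
        lam, right, left = self._eigen()
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, 1.0, out=p)
        return p

    def transition_matrices(self, t) -> np.ndarray:
        """P(r_k * t) for every rate category and every ``t``.

        Returns shape ``(K, S, S)`` for scalar ``t`` or ``(T, K, S, S)``
        for a vector of lengths.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("branch lengths must be nonnegative")
        lam, right, left = self._eigen()
        rates = self.rate_categories.rates
        ex = np.exp(np.multiply.outer(np.multiply.outer(t_arr, rates), lam))
        p = np.einsum("xj,tkj,jy->tkxy", right, ex, left, optimize=True)
        np.clip(p, 0.0, 1.0, out=p)
        if np.isscalar(t) or np.ndim(t) == 0:
            return p[0]
        return p


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) by eigendecomposition of an arbitrary rate matrix."""
    if t < 0:
        raise ValueError(f"branch length must be nonnegative, got {t}")
    lam, v = np.linalg.eig(np.asarray(q, dtype=float))
    p = (v * np.exp(lam * t)[None, :]) @ np.linalg.inv(v)
    p = np.real(p)
    np.clip(p, 0.0, 1.0, out=p)
    return p


def _expand_upper(upper, n):
    s = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    s[iu] = upper
    return s + s.T


def gtr(exch6, freqs, alpha: float = 1.0, ncat: int = 4) -> SubstModel:
    """GTR nucleotide model from the six exchangeabilities (AC AG AT CG CT GT)."""
    exch6 = np.asarray(exch6, dtype=float)
    if exch6.shape != (6,):
        raise ValueError("GTR needs exactly 6 exchangeabilities (AC AG AT CG CT GT)")
    return SubstModel(_expand_upper(exch6, 4), freqs, alpha, ncat, name="GTR")


def jc69(alpha: float = 1.0, ncat: int = 1) -> SubstModel:
    """Jukes-Cantor as the uniform special case of GTR."""
    m = gtr(np.ones(6), np.full(4, 0.25), alpha, ncat)
    m.name = "JC69"
    return m


def lg(alpha: float = 1.0, ncat: int = 4, freqs=None) -> SubstModel:
    """LG amino-acid model (Le & Gascuel 2008), model frequencies by default."""
    return SubstModel(
        _expand_upper(np.array(LG_EXCH_UPPER), 20),
        np.array(LG_FREQS) if freqs is None else np.asarray(freqs, float),
        alpha, ncat, name="LG",
    )


def wag(alpha: float = 1.0, ncat: int = 4, freqs=None) -> SubstModel:
    """WAG amino-acid model (Whelan & Goldman 2001), model frequencies by default."""
    return SubstModel(
        _expand_upper(np.array(WAG_EXCH_UPPER), 20),
        np.array(WAG_FREQS) if freqs is None else np.asarray(freqs, float),
        alpha, ncat, name="WAG",
    )


# ---------------------------------------------------------------------------
# model file i/o

def write_model_file(model: SubstModel) -> str:
    lines = [f"model = {model.name}"]
    if model.name == "GTR" or model.name == "JC69":
        iu = np.triu_indices(4, k=1)
        rates = " ".join(f"{v:.10g}" for v in model.exchangeabilities[iu])
        lines.append(f"rates = {rates}")
        lines.append("freqs = " + " ".join(f"{v:.10g}" for v in model.stationary_freqs))
    lines.append(f"alpha = {model.gamma_shape:.10g}")
    lines.append(f"ncat = {model.n_rate_cats}")
    return "\n".join(lines) + "\n"


def read_model_file(text: str) -> SubstModel:
    """Parse the flat key-value model file.

    Keys: ``model`` (GTR, JC69, LG, WAG), ``rates`` (6 reals, GTR only,
    order AC AG AT CG CT GT), ``freqs`` (4 or 20 reals), ``alpha``, ``ncat``.
    """
    kv = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed model file line: {line!r}")
        k, v = line.split("=", 1)
        kv[k.strip().lower()] = v.strip()
    name = kv.get("model", "GTR").upper()
    alpha = float(kv.get("alpha", 1.0))
    ncat = int(kv.get("ncat", 4))
    freqs = None
    if "freqs" in kv:
        freqs = np.array([float(x) for x in kv["freqs"].split()])
    if name == "LG":
        return lg(alpha, ncat, freqs)
    if name == "WAG":
        return wag(alpha, ncat, freqs)
    if name == "JC69":
        m = jc69(alpha, ncat)
        return m
    if name == "GTR":
        if "rates" not in kv:
            raise ValueError("GTR model file needs a 'rates' line with 6 values")
        rates = np.array([float(x) for x in kv["rates"].split()])
        if freqs is None:
            raise ValueError("GTR model file needs a 'freqs' line with 4 values")
        return gtr(rates, freqs, alpha, ncat)
    raise ValueError(f"unknown model {name!r} (expected GTR, JC69, LG or WAG)")


_PHYML_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


def import_phyml_stats(text: str) -> SubstModel:
    """Best-effort import of a PHYML ``*_phyml_stats`` file.

    Scans for the gamma shape, nucleotide frequencies ``f(A)=...`` and the
    GTR relative rates ``A <-> C`` lines; raises a descriptive error asking
    for a flat model file when the dialect cannot be recognized.
    """
    try:
        alpha_m = re.search(r"Gamma shape parameter\s*[:=]?\s*([0-9.eE+-]+)", text)
        ncat_m = re.search(r"Number of (?:rate )?categories\s*[:=]?\s*(\d+)", text)
        if re.search(r"Model of amino acids substitution\s*[:=]?\s*LG", text):
            return lg(float(alpha_m.group(1)) if alpha_m else 1.0,
                      int(ncat_m.group(1)) if ncat_m else 4)
        if re.search(r"Model of amino acids substitution\s*[:=]?\s*WAG", text):
            return wag(float(alpha_m.group(1)) if alpha_m else 1.0,
                       int(ncat_m.group(1)) if ncat_m else 4)
        freqs = []
        for b in "ACGT":
            m = re.search(rf"f\({b}\)\s*[:=]\s*([0-9.eE+-]+)", text)
            freqs.append(float(m.group(1)))
        rates = []
        for x, y in _PHYML_PAIRS:
            m = re.search(rf"{x}\s*<\s*-\s*>\s*{y}\s*[:=]?\s*([0-9.eE+-]+)", text) or \
                re.search(rf"{x}\s*<->\s*{y}\s*[:=]?\s*([0-9.eE+-]+)", text)
            rates.append(float(m.group(1)))
        return gtr(rates, freqs,
                   float(alpha_m.group(1)) if alpha_m else 1.0,
                   int(ncat_m.group(1)) if ncat_m else 4)
    except (AttributeError, TypeError) as exc:
        raise ValueError(
            "could not recognize PHYML statistics dialect; please write a flat "
            "model file (model=/rates=/freqs=/alpha=/ncat=) instead"
        ) from exc


def import_raxml_info(text: str) -> SubstModel:
    """Best-effort import of a RAxML ``RAxML_info`` file (GTR+Γ or LG/WAG)."""
    try:
        alpha_m = re.search(r"alpha(?:\[0\])?\s*[:=]\s*([0-9.eE+-]+)", text)
        alpha = float(alpha_m.group(1)) if alpha_m else 1.0
        if re.search(r"\bLG\b", text) and "rate A <-> C" not in text:
            return lg(alpha, 4)
        if re.search(r"\bWAG\b", text) and "rate A <-> C" not in text:
            return wag(alpha, 4)
        rates = []
        for x, y in _PHYML_PAIRS:
            m = re.search(rf"rate {x} <-> {y}\s*[:=]\s*([0-9.eE+-]+)", text)
            rates.append(float(m.group(1)))
        freqs = []
        for b in "ACGT":
            m = re.search(rf"freq pi\({b}\)\s*[:=]\s*([0-9.eE+-]+)", text)
            freqs.append(float(m.group(1)))
        return gtr(rates, freqs, alpha, 4)
    except (AttributeError, TypeError) as exc:
        raise ValueError(
            "could not recognize RAxML info dialect; please write a flat "
            "model file (model=/rates=/freqs=/alpha=/ncat=) instead"
        ) from exc
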