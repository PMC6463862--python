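"""Pairwise ortholog divergence and the fixed- vs free-omega neutrality test.

The core is a Goldman-Yang style codon substitution model over the 61 sense
codons of the universal code: instantaneous changes are single-nucleotide
only, scaled by kappa for transitions and omega for nonsynonymous changes,
with stationary codon frequencies (equal or F3x4).  The neutrality test
fits the model twice — omega fixed at 1 and omega free — and compares
2*(lnL_free - lnL_fixed) against the chi-square(1) 5% critical value 2.71.
The Nei-Gojobori (1986) counting estimator with Jukes-Cantor correction is
provided as an independent companion estimate of dN and dS.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

import numpy as np
from scipy import optimize, stats
from scipy.linalg import expm

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODONS = tuple(sorted(standard_dna_table.forward_table))  # 61 sense codons
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = {c: standard_dna_table.forward_table[c] for c in CODONS}

# 5% critical value for the one-degree-of-freedom test as used in codeml
# practice: the 5% point of the 1/2*chi2(0) + 1/2*chi2(1) mixture, i.e. the
# chi2(1) upper 10% point, 2.71.
NEUTRALITY_LRT_THRESHOLD = round(float(stats.chi2.isf(2 * 0.05, df=1)), 2)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


def _single_change_topology():
    """Index arrays over codon pairs differing at exactly one nucleotide."""
    src, dst, ts, syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            src.append(i)
            dst.append(j)
            ts.append(is_transition(ci[k], cj[k]))
            syn.append(CODON_AA[ci] == CODON_AA[cj])
    return (np.array(src), np.array(dst), np.array(ts, dtype=bool),
            np.array(syn, dtype=bool))

_SRC, _DST, _TS, _SYN = _single_change_topology()


@dataclass
class CodonModelParams:
    """GY94 parameters: branch length t (expected substitutions per codon),
    transition/transversion ratio kappa, dN/dS ratio omega, and stationary
    codon frequencies over the 61 sense codons."""

    t: float
    kappa: float
    omega: float
    codon_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.t < 0 or self.kappa <= 0 or self.omega < 0:
            raise ValueError("require t >= 0, kappa > 0, omega >= 0")
        if self.codon_freqs.shape != (61,) or not np.isclose(self.codon_freqs.sum(), 1):
            raise ValueError("codon_freqs must be 61 values summing to 1")


@dataclass
class CodonAlignment:
    """Two in-frame codon sequences with unusable columns dropped pairwise."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    n_dropped: int = 0
    had_internal_stop: bool = False

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def pair_counts(self) -> np.ndarray:
        counts = np.zeros((61, 61))
        for ca, cb in zip(self.codons_a, self.codons_b):
            counts[CODON_INDEX[ca], CODON_INDEX[cb]] += 1
        return counts


@dataclass
class NG86Result:
    dN: float
    dS: float
    omega: float          # nan when dS == 0
    pN: float
    pS: float
    syn_sites: float
    nonsyn_sites: float
    saturated: bool = False


@dataclass
class NeutralityTestResult:
    """One row of the orthologous-pair neutrality test."""

    pair_id: str
    lnML1: float          # omega fixed at 1
    lnML2: float          # omega free
    LR: float
    omega_hat: float
    dN: float
    dS: float
    classification: str   # "Neutral" or "Non-neutral"
    kappa_hat: float = float("nan")
    t_hat: float = float("nan")


def build_codon_alignment(seq_a: str, seq_b: str) -> CodonAlignment:
    """Split two equal-length in-frame sequences into codon columns,
    dropping any column with a gap, an ambiguous base, or a stop codon in
    either sequence (drop count reported)."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("length not divisible by 3")
    keep_a, keep_b, dropped, stop_seen = [], [], 0, False
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca in CODON_INDEX and cb in CODON_INDEX:
            keep_a.append(ca)
            keep_b.append(cb)
        else:
            dropped += 1
            if ca in STOP_CODONS or cb in STOP_CODONS:
                stop_seen = True
    return CodonAlignment(tuple(keep_a), tuple(keep_b), dropped, stop_seen)


def equal_codon_freqs() -> np.ndarray:
    return np.full(61, 1.0 / 61)


def f3x4_freqs(aln: CodonAlignment, eps: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies: products of position-specific nucleotide
    frequencies estimated from both sequences, stops removed, renormalized.
    A small pseudo-frequency keeps every sense codon strictly positive."""
    counts = np.zeros((3, 4))
    for seq in (aln.codons_a, aln.codons_b):
        for codon in seq:
            for k, base in enumerate(codon):
                counts[k, _BASES.index(base)] += 1
    freqs = (counts + eps) / (counts + eps).sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, _BASES.index(c[0])]
                   * freqs[1, _BASES.index(c[1])]
                   * freqs[2, _BASES.index(c[2])] for c in CODONS])
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray,
                      ) -> np.ndarray:
    """GY94 rate matrix over sense codons, scaled to mean rate 1 (one
    expected substitution per codon per unit branch length)."""
    pi = np.asarray(codon_freqs, dtype=float)
    rates = pi[_DST] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q = np.zeros((61, 61))
    Q[_SRC, _DST] = rates
    Q[np.diag_indices(61)] = -Q.sum(axis=1)
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / mean_rate


def flux_proportions(kappa: float, omega: float, codon_freqs: np.ndarray,
                     ) -> tuple[float, float]:
    """Proportions of the stationary substitution flux that are
    nonsynonymous and synonymous under the (unscaled) GY94 rates."""
    pi = np.asarray(codon_freqs, dtype=float)
    rates = pi[_SRC] * pi[_DST] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    total = rates.sum()
    rho_n = float(rates[~_SYN].sum() / total)
    return rho_n, 1.0 - rho_n


def gy94_loglik(aln: CodonAlignment, params: CodonModelParams,
                pair_counts: np.ndarray | None = None) -> float:
    """Log-likelihood of the codon pair under the GY94 model:
    sum over columns of ln(pi_a * P(t)[a, b])."""
    pi = params.codon_freqs
    Q = build_rate_matrix(params.kappa, params.omega, pi)
    P = expm(Q * params.t)
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite transition matrix")
    if pair_counts is None:
        pair_counts = aln.pair_counts()
    with np.errstate(divide="ignore"):
        logterm = np.log(np.clip(pi[:, None] * P, 1e-300, None))
    return float((pair_counts * logterm).sum())


_FIT_BOUNDS = {"t": (1e-6, 20.0), "kappa": (0.01, 50.0), "omega": (1e-4, 20.0)}
_T_STARTS = (0.1, 0.5)
_KAPPA_START = 2.0
_OMEGA_STARTS = (0.3, 1.5)


def fit_codon_model(aln: CodonAlignment, fix_omega: float | None = None,
                    codon_freqs: np.ndarray | str = "f3x4",
                    ) -> tuple[CodonModelParams, float]:
    """Maximize the pairwise GY94 likelihood over (t, kappa[, omega]).

    Multi-start bounded L-BFGS-B in log-parameter space with a fixed,
    deterministic start grid; the best of all converged starts is returned.
    """
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    if isinstance(codon_freqs, str):
        if codon_freqs == "f3x4":
            pi = f3x4_freqs(aln)
        elif codon_freqs == "equal":
            pi = equal_codon_freqs()
        else:
            raise ValueError(f"unknown codon frequency model {codon_freqs!r}")
    else:
        pi = np.asarray(codon_freqs, dtype=float)
    counts = aln.pair_counts()
    free_omega = fix_omega is None
    names = ["t", "kappa"] + (["omega"] if free_omega else [])
    bounds = [np.log(_FIT_BOUNDS[p]) for p in names]

    def negloglik(logx: np.ndarray) -> float:
        x = np.exp(logx)
        omega = x[2] if free_omega else fix_omega
        params = CodonModelParams(x[0], x[1], omega, pi)
        return -gy94_loglik(aln, params, pair_counts=counts)

    starts = [[t0, _KAPPA_START] + ([w0] if free_omega else [])
              for t0 in _T_STARTS
              for w0 in (_OMEGA_STARTS if free_omega else [None])]
    best = None
    for x0 in starts:
        res = optimize.minimize(negloglik, np.log(np.array(x0, dtype=float)),
                                method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("codon-model optimization failed from every start")
    x = np.exp(best.x)
    omega = x[2] if free_omega else fix_omega
    return CodonModelParams(float(x[0]), float(x[1]), float(omega), pi), float(-best.fun)


def ml_dnds(params: CodonModelParams) -> tuple[float, float]:
    """dN and dS implied by fitted GY94 parameters.

    The scaled flux t splits into nonsynonymous and synonymous parts
    (rho_N, rho_S); site proportions f_N, f_S are the corresponding flux
    proportions under omega = 1.  Then dN = t*rho_N / (3*f_N) and
    dS = t*rho_S / (3*f_S), so dN/dS = omega by construction.
    """
    rho_n, rho_s = flux_proportions(params.kappa, params.omega, params.codon_freqs)
    f_n, f_s = flux_proportions(params.kappa, 1.0, params.codon_freqs)
    if f_s == 0:
        raise ZeroDivisionError("no synonymous sites under the model")
    dN = params.t * rho_n / (3.0 * f_n)
    dS = params.t * rho_s / (3.0 * f_s)
    return dN, dS


def neutrality_lrt(lnML1: float, lnML2: float,
                   threshold: float = NEUTRALITY_LRT_THRESHOLD,
                   tol: float = 1e-6) -> tuple[float, str]:
    """Likelihood-ratio statistic 2*(lnML2 - lnML1) and its call.

    lnML1 is the omega-fixed-at-1 (neutral) model, lnML2 the free-omega
    model; the free model nests the fixed one, so the statistic is
    non-negative up to optimizer noise.  Classification is "Neutral" iff
    LR < threshold (chi-square(1) 5% critical value).
    """
    LR = 2.0 * (lnML2 - lnML1)
    if LR < -tol:
        raise ValueError(f"lnML2 < lnML1 (LR = {LR:.3g}): optimizer failure")
    LR = max(LR, 0.0)
    return LR, ("Neutral" if LR < threshold else "Non-neutral")


def evaluate_pair_neutrality(aln: CodonAlignment, pair_id: str = "pair",
                         codon_freqs: np.ndarray | str = "f3x4",
                         threshold: float = NEUTRALITY_LRT_THRESHOLD,
                         ) -> NeutralityTestResult:
    """Run the full fixed- vs free-omega test on one ortholog pair."""
    _, lnML1 = fit_codon_model(aln, fix_omega=1.0, codon_freqs=codon_freqs)
    params, lnML2 = fit_codon_model(aln, codon_freqs=codon_freqs)
    if lnML2 < lnML1:   # same model family; keep the nested bound exact
        lnML2 = lnML1
    LR, call = neutrality_lrt(lnML1, lnML2, threshold=threshold)
    dN, dS = ml_dnds(params)
    return NeutralityTestResult(pair_id, lnML1, lnML2, LR, params.omega, dN, dS,
                                call, params.kappa, params.t)


# --- Nei-Gojobori (1986) counting method -------------------------------------

def _ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon: at each position
    the fraction of the three single-nucleotide changes that are synonymous
    (changes to stop codons count as nonsynonymous)."""
    syn = 0.0
    for k in range(3):
        for base in _BASES:
            if base == codon[k]:
                continue
            alt = codon[:k] + base + codon[k + 1:]
            if alt not in STOP_CODONS and CODON_AA[alt] == CODON_AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _ng86_diff_counts(ca: str, cb: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    with equal weight over minimal mutational pathways; pathways passing
    through stop codons are excluded (all pathways used as fallback if
    every one hits a stop)."""
    positions = [k for k in range(3) if ca[k] != cb[k]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        current, sd, nd, through_stop = ca, 0.0, 0.0, False
        for k in order:
            nxt = current[:k] + cb[k] + current[k + 1:]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                through_stop = True
            if (current not in STOP_CODONS and nxt not in STOP_CODONS
                    and CODON_AA[current] == CODON_AA[nxt]):
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((through_stop, sd, nd))
    usable = [(s, n) for stop, s, n in paths if not stop]
    if not usable:
        usable = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(aln: CodonAlignment) -> NG86Result:
    """Nei-Gojobori counting estimates of dN and dS.

    Site counts are averaged over both sequences; differences use equal
    weighting over minimal pathways.  Proportions are Jukes-Cantor
    corrected; omega = dN/dS, nan when dS = 0; the result is flagged
    saturated when a proportion reaches the correction's domain edge.
    """
    if aln.n_codons < 1:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sa, na = _ng86_site_counts(ca)
        sb, nb = _ng86_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _ng86_diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    saturated = bool(np.isnan(dS) or np.isnan(dN))
    omega = dN / dS if dS and dS > 0 else float("nan")
    return NG86Result(dN, dS, omega, pN, pS, S, N, saturated)
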