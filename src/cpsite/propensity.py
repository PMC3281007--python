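"""Sequence/secondary-structure pattern statistics around cleavage points.

A circular-permutation site is represented by the 2k-residue segment
surrounding its cleavage point (default k = 3, a 6-residue window).  Pattern
occurrence frequencies in a site group are contrasted with a background
group through a two-sided permutation test, and each pattern receives a
significance-weighted propensity score

    S_p = (1 - p) * log2((f_e + eps) / (f_c + eps))

where f_e/f_c are the mean per-polypeptide frequencies in the experimental
(site) and comparison (background) groups and eps is a small
pseudo-frequency guarding against division by zero.  Positive scores mark
patterns enriched at viable sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .descriptors import HYDROPHOBIC, HYDROPHILIC, NEUTRAL
from .structure import SSE8, StructureTable

logger = logging.getLogger("cpsite")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 3-class physiochemical map: hydrophobic / hydrophilic / neutral.
CLASS3 = {}
for _aa in HYDROPHOBIC:
    CLASS3[_aa] = "b"  # hydrophobic
for _aa in HYDROPHILIC:
    CLASS3[_aa] = "l"  # hydrophilic
for _aa in NEUTRAL:
    CLASS3[_aa] = "n"  # neutral

#: 5-class side-chain map: nonpolar aliphatic / aromatic / polar uncharged /
#: positively charged / negatively charged.
CLASS5 = {}
for _aa in "GAPVLIM":
    CLASS5[_aa] = "a"  # nonpolar aliphatic
for _aa in "FYW":
    CLASS5[_aa] = "r"  # aromatic
for _aa in "STCNQ":
    CLASS5[_aa] = "u"  # polar uncharged
for _aa in "KRH":
    CLASS5[_aa] = "+"
for _aa in "DE":
    CLASS5[_aa] = "-"


@dataclass
class PatternCatalog:
    """A symbol alphabet over which pattern frequencies are counted.

    ``symbol_map`` translates raw sequence letters into catalog symbols
    (identity when None).  ``arity`` = 1 counts single symbols; ``arity`` = 2
    counts symbol pairs separated by ``gap`` positions (gap = 1 means
    adjacent di-residue patterns).
    """

    name: str
    alphabet: str
    symbol_map: Optional[Dict[str, str]] = None
    arity: int = 1
    gap: int = 1

    def __post_init__(self):
        if self.arity not in (1, 2):
            raise ValueError("arity must be 1 or 2")
        if self.arity == 2 and self.gap < 1:
            raise ValueError("pair patterns need gap >= 1")
        if self.symbol_map is not None:
            mapped = set(self.symbol_map.values())
            if not mapped <= set(self.alphabet):
                raise ValueError("symbol_map maps outside the alphabet")

    def encode(self, text: str) -> str:
        if self.symbol_map is None:
            return text
        return "".join(self.symbol_map.get(c, c) for c in text)

    @property
    def patterns(self) -> List[str]:
        if self.arity == 1:
            return list(self.alphabet)
        return [a + b for a in self.alphabet for b in self.alphabet]

    @property
    def n_patterns(self) -> int:
        return len(self.alphabet) ** self.arity


def aa_catalog() -> PatternCatalog:
    return PatternCatalog("aa", AMINO_ACIDS)


def class3_catalog() -> PatternCatalog:
    return PatternCatalog("class3", "bln", symbol_map=dict(CLASS3))


def class5_catalog() -> PatternCatalog:
    return PatternCatalog("class5", "aru+-", symbol_map=dict(CLASS5))


def sse_catalog() -> PatternCatalog:
    return PatternCatalog("sse8", SSE8)


def di_residue_catalog(base: Optional[PatternCatalog] = None) -> PatternCatalog:
    base = base or aa_catalog()
    return PatternCatalog(
        f"di_{base.name}", base.alphabet, symbol_map=base.symbol_map,
        arity=2, gap=1,
    )


def gapped_pair_catalog(gap: int, base: Optional[PatternCatalog] = None) -> PatternCatalog:
    base = base or aa_catalog()
    return PatternCatalog(
        f"pair_g{gap}_{base.name}", base.alphabet, symbol_map=base.symbol_map,
        arity=2, gap=gap,
    )


@dataclass
class Segment:
    """The 2k-residue window representing one CP site.

    Covers seq positions site-k .. site+k-1, truncated at chain ends; the
    cleavage point sits between positions site-1 and site.
    """

    protein_id: str
    site_position: int
    k: int
    aa: str
    sse: str = ""
    positions: Tuple[int, int] = (0, 0)  # first, last seq_position covered


def extract_segments(
    source: Union[StructureTable, str],
    sites: Iterable[int],
    k: int = 3,
    sse: Optional[str] = None,
    protein_id: str = "protein",
) -> List[Segment]:
    """Window the chain around each cleavage point.

    ``source`` is a StructureTable (sequence and SSE taken from it) or a
    plain amino-acid string.  Each segment covers positions site-k ..
    site+k-1; positions off either end are omitted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(source, StructureTable):
        seq = source.sequence
        sse = sse if sse is not None else source.sse_string
        protein_id = source.protein_id
    else:
        seq = source
    n = len(seq)
    out = []
    for site in sites:
        if not 1 < site <= n:
            raise ValueError(f"site {site} out of range for chain length {n}")
        lo = max(1, site - k)
        hi = min(n, site + k - 1)
        out.append(
            Segment(
                protein_id=protein_id,
                site_position=site,
                k=k,
                aa=seq[lo - 1:hi],
                sse=(sse[lo - 1:hi] if sse else ""),
                positions=(lo, hi),
            )
        )
    return out


def pattern_frequencies(polypeptide: str, catalog: PatternCatalog) -> Dict[str, float]:
    """Per-pattern occurrence frequency within one polypeptide.

    Single symbols: count / length.  Pairs with gap g: count of (s_i,
    s_{i+g}) / (length - g).  Too-short polypeptides yield all-zero
    frequencies.
    """
    if len(polypeptide) == 0:
        raise ValueError("empty polypeptide")
    encoded = catalog.encode(polypeptide)
    freqs = {p: 0.0 for p in catalog.patterns}
    if catalog.arity == 1:
        denom = len(encoded)
        for c in encoded:
            if c in freqs:
                freqs[c] += 1.0
    else:
        g = catalog.gap
        denom = len(encoded) - g
        if denom <= 0:
            return freqs
        for i in range(denom):
            pat = encoded[i] + encoded[i + g]
            if pat in freqs:
                freqs[pat] += 1.0
    for p in freqs:
        freqs[p] /= denom
    return freqs


def frequency_table(
    group: Sequence[str], catalog: PatternCatalog
) -> pd.DataFrame:
    """Rows = polypeptides, columns = patterns, values = frequencies."""
    if len(group) == 0:
        raise ValueError("empty group")
    return pd.DataFrame([pattern_frequencies(s, catalog) for s in group])


def bootstrap_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap resample of size n (with replacement)."""
    return rng.integers(0, n, size=n)


def bootstrap_mean_occurrence(
    group: Sequence[str],
    catalog: PatternCatalog,
    m: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap-aggregated mean pattern occurrence for a polypeptide group.

    Draws ``m`` resamples of the n polypeptides with replacement (resample
    size n' = n); for each resample the group-mean frequency of every pattern
    is recorded.  Returns per-pattern mean and standard deviation of the
    bootstrap means.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    freqs = frequency_table(group, catalog).to_numpy()
    n = freqs.shape[0]
    rng = np.random.default_rng(seed)
    means = np.empty((m, freqs.shape[1]))
    for b in range(m):
        means[b] = freqs[bootstrap_indices(n, rng)].mean(axis=0)
    return pd.DataFrame(
        {
            "pattern": catalog.patterns,
            "mean": means.mean(axis=0),
            "sd": means.std(axis=0, ddof=1) if m > 1 else np.zeros(freqs.shape[1]),
        }
    ).set_index("pattern")


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_LIMIT = 10_000


def permutation_test_values(
    values_e: np.ndarray,
    values_c: np.ndarray,
    T: int = 99_999,
    seed: int = 0,
) -> Tuple[float, float]:
    """Two-sided permutation test for a difference of group means.

    The statistic is theta = mean(values_e) - mean(values_c).  Group labels
    are permuted without replacement, preserving group sizes; the p-value is
    the fraction of resampled |theta*| >= |theta|, with the +1 correction
    (t + 1)/(T + 1) under Monte-Carlo sampling.  When the number of distinct
    relabelings C(N, n_e) is at most 10,000 the full enumeration is used
    instead and the p-value is exact.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    values_e = np.asarray(values_e, dtype=float)
    values_c = np.asarray(values_c, dtype=float)
    if len(values_e) == 0 or len(values_c) == 0:
        raise ValueError("both groups must be non-empty")
    n_e, n_c = len(values_e), len(values_c)
    pooled = np.concatenate([values_e, values_c])
    total = pooled.sum()
    theta = values_e.mean() - values_c.mean()
    abs_theta = abs(theta)
    tol = 1e-12

    def theta_from_sum(s_e: np.ndarray) -> np.ndarray:
        return s_e / n_e - (total - s_e) / n_c

    if math.comb(n_e + n_c, n_e) <= EXACT_ENUMERATION_LIMIT:
        count = 0
        n_rounds = 0
        for combo in combinations(range(n_e + n_c), n_e):
            s = pooled[list(combo)].sum()
            if abs(theta_from_sum(s)) >= abs_theta - tol:
                count += 1
            n_rounds += 1
        return theta, count / n_rounds

    rng = np.random.default_rng(seed)
    n = n_e + n_c
    t_count = 0
    done = 0
    levels, level_counts = np.unique(pooled, return_counts=True)
    use_levels = len(levels) <= 1024
    chunk = max(1, min(T, 20_000_000 // max(n, 1)))
    while done < T:
        b = min(chunk, T - done)
        if use_levels:
            # the statistic depends only on the subset sum, whose level
            # composition under uniform relabeling is multivariate
            # hypergeometric -- O(levels) per draw instead of O(N)
            k = rng.multivariate_hypergeometric(level_counts, n_e, size=b)
            s = k @ levels
        else:
            u = rng.random((b, n))
            order = np.argpartition(u, n_e - 1, axis=1)[:, :n_e]
            s = pooled[order].sum(axis=1)
        t_count += int(np.sum(np.abs(theta_from_sum(s)) >= abs_theta - tol))
        done += b
    return theta, (t_count + 1) / (T + 1)


def permutation_test(
    group_e: Sequence[str],
    group_c: Sequence[str],
    pattern: str,
    catalog: PatternCatalog,
    T: int = 99_999,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permutation test on the per-polypeptide frequency of one pattern."""
    fe = frequency_table(group_e, catalog)[pattern].to_numpy()
    fc = frequency_table(group_c, catalog)[pattern].to_numpy()
    return permutation_test_values(fe, fc, T=T, seed=seed)


# ---------------------------------------------------------------------------
# Propensity score
# ---------------------------------------------------------------------------

def pseudo_frequency(
    freqs_e: np.ndarray, freqs_c: np.ndarray, total_length: int
) -> float:
    """Pseudo-frequency eps = half the sum of the smallest nonzero
    per-polypeptide frequencies of the pattern in each group.

    A group in which the pattern never occurs contributes the fallback
    1 / (summed polypeptide length) instead of a nonzero minimum.
    """
    fallback = 1.0 / max(total_length, 1)
    mins = []
    for f in (np.asarray(freqs_e), np.asarray(freqs_c)):
        nz = f[f > 0]
        mins.append(nz.min() if len(nz) else fallback)
    return 0.5 * (mins[0] + mins[1])


def propensity_score(
    f_e: float, f_c: float, p: float, epsilon: float
) -> float:
    """Significance-weighted log-ratio propensity score.

    S_p = (1 - p) * log2((f_e + eps)/(f_c + eps)); zero when the
    frequencies agree or when the permutation p-value is 1.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if f_e < 0 or f_c < 0:
        raise ValueError("frequencies must be nonnegative")
    w = 1.0 - p
    return w * math.log2((f_e + epsilon) / (f_c + epsilon))


@dataclass
class PropensityResult:
    pattern: str
    f_e: float
    f_c: float
    n_e: int
    n_c: int
    p: float
    weight: float
    epsilon: float
    s_p: float


def score_table(
    group_e: Sequence[str],
    group_c: Sequence[str],
    catalog: PatternCatalog,
    T: int = 99_999,
    seed: int = 0,
    patterns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Propensity scores for every pattern of a catalog.

    Returns a frame indexed by pattern with columns f_e, f_c, n_e, n_c, p,
    weight, epsilon, s_p.  ``patterns`` restricts the scan (the permutation
    test dominates the cost).
    """
    tab_e = frequency_table(group_e, catalog)
    tab_c = frequency_table(group_c, catalog)
    len_e = sum(len(s) for s in group_e)
    len_c = sum(len(s) for s in group_c)
    gap = catalog.gap if catalog.arity == 2 else 0
    denom_e = np.asarray([max(len(s) - gap, 0) for s in group_e], dtype=float)
    denom_c = np.asarray([max(len(s) - gap, 0) for s in group_c], dtype=float)
    rows = []
    scan = list(patterns) if patterns is not None else catalog.patterns
    rng = np.random.default_rng(seed)
    for pat in scan:
        fe = tab_e[pat].to_numpy()
        fc = tab_c[pat].to_numpy()
        _, p = permutation_test_values(
            fe, fc, T=T, seed=int(rng.integers(0, 2**31 - 1))
        )
        eps = pseudo_frequency(fe, fc, len_e + len_c)
        f_e, f_c = fe.mean(), fc.mean()
        rows.append(
            PropensityResult(
                pattern=pat,
                f_e=f_e,
                f_c=f_c,
                n_e=int(round(float(np.dot(fe, denom_e)))),
                n_c=int(round(float(np.dot(fc, denom_c)))),
                p=p,
                weight=1.0 - p,
                epsilon=eps,
                s_p=propensity_score(f_e, f_c, p, eps),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("pattern")
    return df


# ---------------------------------------------------------------------------
# Per-residue propensity features
# ---------------------------------------------------------------------------

#: Feature name -> catalog factory for the per-residue propensity features.
PROPENSITY_FEATURES = {
    "R_aa": aa_catalog,
    "R_aat3": class3_catalog,
    "R_aat5": class5_catalog,
    "R_sse": sse_catalog,
}


def residue_propensity_features(
    structure: StructureTable,
    score_tables: Dict[str, Dict[str, float]],
    k: int = 3,
) -> pd.DataFrame:
    """Windowed mean propensity scores per candidate site position.

    ``score_tables`` maps feature names (R_aa, R_aat3, R_aat5, R_sse) to
    {symbol: S_p} lookups.  For each residue position s, the corresponding
    feature is the mean score of the catalog symbols within the 2k window
    around the cleavage point at s, truncated at the termini.  Symbols absent
    from a table score 0 (with a warning).
    """
    n = len(structure)
    out = {}
    warned = set()
    for feat, factory in PROPENSITY_FEATURES.items():
        if feat not in score_tables:
            continue
        catalog = factory()
        table = score_tables[feat]
        raw = structure.sse_string if feat == "R_sse" else structure.sequence
        encoded = catalog.encode(raw)
        values = np.zeros(n)
        for s in range(1, n + 1):
            lo = max(1, s - k)
            hi = min(n, s + k - 1)
            window = encoded[lo - 1:hi]
            scores = []
            for sym in window:
                if sym not in table:
                    if (feat, sym) not in warned:
                        logger.warning(
                            "symbol %r missing from %s score table; scored 0",
                            sym, feat,
                        )
                        warned.add((feat, sym))
                    scores.append(0.0)
                else:
                    scores.append(table[sym])
            values[s - 1] = float(np.mean(scores)) if scores else 0.0
        out[feat] = values
    return pd.DataFrame(out)


def pattern_coverage(
    segments: Sequence[Segment], catalog: PatternCatalog
) -> float:
    """Observed distinct patterns over the theoretical maximum.

    E.g. 300 observed di-residue combinations out of 20 x 20 = 400 possible
    gives coverage 0.75.
    """
    observed = set()
    for seg in segments:
        text = seg.sse if catalog.name.endswith("sse8") else seg.aa
        encoded = catalog.encode(text)
        if catalog.arity == 1:
            observed.update(c for c in encoded if c in catalog.alphabet)
        else:
            g = catalog.gap
            for i in range(max(0, len(encoded) - g)):
                pat = encoded[i] + encoded[i + g]
                if pat[0] in catalog.alphabet and pat[1] in catalog.alphabet:
                    observed.add(pat)
    return len(observed) / catalog.n_patterns
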