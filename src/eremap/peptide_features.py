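"""Downstream analytics on validated peptides.

Expression of a peptide's coding sequence in an RNA-seq sample is
summarized as rphm — reads per hundred million sequenced:

    r_overlap = min over the coding sequence's 24-mers of the sample's
                canonical k-mer counts
    rphm      = r_overlap / total_reads * 1e8

A tissue expresses a peptide significantly when the tissue mean of
log10(rphm + 1) exceeds log10(10 + 1).  The module also measures
methylation/expression coupling around the coding locus, amino-acid
composition (overall and positional), and homology to a viral peptide
database via exact Smith-Waterman local alignment under PAM30 with
affine gaps, with a bootstrap test against canonical peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .eremap_validation import KmerCountTable, mcs_min_occurrence
from .expression import pearson
from .io_formats import AMINO_ACIDS

__all__ = [
    "RphmProfile",
    "rphm",
    "rphm_profile",
    "RPHM_SIGNIFICANCE",
    "methylation_correlation",
    "aa_frequencies",
    "positional_aa_frequencies",
    "AlignmentHit",
    "local_align",
    "percent_identity",
    "viral_homology_test",
]

RPHM_SIGNIFICANCE = 10.0  # rphm; compared on the log10(x+1) scale
METHYLATION_WINDOW = 5000  # nt on either side of the coding locus

_PAM30 = substitution_matrices.load("PAM30")
_PAM30_DICT: dict[tuple[str, str], float] = {
    (a, b): float(_PAM30[a][b])
    for a in _PAM30.alphabet
    for b in _PAM30.alphabet
}


def rphm(r_overlap: int, total_reads: int) -> float:
    """Reads per hundred million: r_overlap / total * 1e8."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    # multiply first: keeps round counts exact (3 / 2e8 * 1e8 != 1.5 in
    # binary floating point, but 3 * 1e8 / 2e8 is)
    return r_overlap * 1e8 / total_reads


@dataclass
class RphmProfile:
    peptide: str
    r_overlap: dict[str, int]  # per sample
    rphm: dict[str, float]  # per sample
    tissue_log_mean: dict[str, float]  # mean log10(rphm+1) per tissue
    significant: dict[str, bool]  # per tissue


def rphm_profile(
    mcs_set: Sequence[str],
    sample_kmer_tables: Mapping[str, KmerCountTable],
    sample_total_reads: Mapping[str, int],
    sample_to_tissue: Mapping[str, str],
    peptide: str = "",
    significance_rphm: float = RPHM_SIGNIFICANCE,
    log_scale: bool = True,
) -> RphmProfile:
    """Expression profile of a peptide's coding sequence(s) across samples.

    Per sample, r_overlap is the best (maximal) minimal 24-mer count
    over the peptide's coding sequences — 0 whenever any k-mer of every
    MCS is absent.  Tissue summaries average log10(rphm + 1) over the
    tissue's samples and flag tissues above the significance threshold
    (``log_scale=False`` compares plain mean rphm instead).
    """
    if not mcs_set:
        raise ValueError("empty coding-sequence set")
    r_overlap: dict[str, int] = {}
    values: dict[str, float] = {}
    for sample, table in sample_kmer_tables.items():
        best = max(mcs_min_occurrence(m, table) for m in mcs_set)
        r_overlap[sample] = best
        values[sample] = rphm(best, sample_total_reads[sample])
    tissue_samples: dict[str, list[str]] = {}
    for s in values:
        tissue_samples.setdefault(sample_to_tissue[s], []).append(s)
    log_mean = {}
    significant = {}
    for tissue, samples in tissue_samples.items():
        if log_scale:
            m = float(np.mean([np.log10(values[s] + 1) for s in samples]))
            cutoff = np.log10(significance_rphm + 1)
        else:
            m = float(np.mean([values[s] for s in samples]))
            cutoff = significance_rphm
        log_mean[tissue] = m
        significant[tissue] = bool(m > cutoff)
    return RphmProfile(peptide, r_overlap, values, log_mean, significant)


def methylation_correlation(
    rphm_per_sample: Mapping[str, float],
    probes: pd.DataFrame,
    locus_chrom: str,
    locus_start: int,
    locus_end: int,
    window: int = METHYLATION_WINDOW,
) -> pd.DataFrame:
    """Pearson r between peptide rphm and beta of each nearby probe.

    Probes qualify when within ``window`` nt of either end of the
    coding locus.  Returns one row per qualifying probe (probe_id,
    distance, r, n); an empty frame when no probe is in the window.
    """
    samples = [s for s in rphm_per_sample if s in probes.columns]
    if len(samples) < 3:
        raise ValueError("methylation correlation needs >= 3 matched samples")
    rows = []
    for _, probe in probes.iterrows():
        if probe["chrom"] != locus_chrom:
            continue
        pos = int(probe["pos"])
        distance = max(locus_start - pos, pos - (locus_end - 1), 0)
        if distance > window:
            continue
        x = [rphm_per_sample[s] for s in samples]
        y = [float(probe[s]) for s in samples]
        try:
            r = pearson(x, y)
        except ValueError:
            r = float("nan")
        rows.append(
            {"probe_id": probe["probe_id"], "distance": distance, "r": r,
             "n": len(samples)}
        )
    return pd.DataFrame(rows, columns=["probe_id", "distance", "r", "n"])


# ---------------------------------------------------------------------------
# amino-acid composition


def aa_frequencies(peptides: Sequence[str]) -> pd.Series:
    """Overall usage frequency of the 20 amino acids (sums to 1)."""
    if not peptides:
        raise ValueError("empty peptide set")
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    total = 0
    for p in peptides:
        for aa in p:
            counts[aa] += 1
            total += 1
    return counts / total


def positional_aa_frequencies(
    peptides: Sequence[str],
    lengths: Sequence[int] = (8, 9, 10, 11),
    min_count: int = 3,
) -> tuple[dict[int, pd.DataFrame], list[int]]:
    """Per-position amino-acid frequencies within each length bin.

    Returns ({length: position x amino-acid frequency frame}, dropped
    lengths).  Bins with fewer than ``min_count`` peptides are dropped
    and reported — a handful of peptides cannot support positional
    frequencies.
    """
    out: dict[int, pd.DataFrame] = {}
    dropped: list[int] = []
    for L in lengths:
        subset = [p for p in peptides if len(p) == L]
        if len(subset) < min_count:
            dropped.append(L)
            continue
        mat = pd.DataFrame(
            0.0, index=range(1, L + 1), columns=list(AMINO_ACIDS)
        )
        for p in subset:
            for i, aa in enumerate(p):
                mat.loc[i + 1, aa] += 1
        out[L] = mat / len(subset)
    return out, dropped


# ---------------------------------------------------------------------------
# local alignment


@dataclass
class AlignmentHit:
    query: str
    subject: str
    score: float
    length: int  # L_a, aligned columns including gaps
    matches: int  # identical aligned pairs

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def local_align(
    query: str,
    subject: str,
    matrix: Mapping[tuple[str, str], float] | None = None,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment with affine gaps.

    A gap of length g costs ``gap_open + gap_extend * g``.  Exact
    dynamic programming — at 8-11-mer scale there is no reason to seed
    heuristically.  Returns the best-scoring hit; an all-negative
    substitution landscape yields the empty alignment with score 0.
    """
    sub = matrix if matrix is not None else _PAM30_DICT
    n, m = len(query), len(subject)
    NEG = float("-inf")
    # M: column is an aligned pair; X: gap column in subject (consumes
    # query); Y: gap column in query (consumes subject)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = {
        "M": [[None] * (m + 1) for _ in range(n + 1)],
        "X": [[None] * (m + 1) for _ in range(n + 1)],
        "Y": [[None] * (m + 1) for _ in range(n + 1)],
    }
    best, best_pos, best_state = 0.0, None, None
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            # aligned pair: extend any state or start fresh (local)
            prev_val, prev_state = 0.0, None
            for s, grid in (("M", M), ("X", X), ("Y", Y)):
                if grid[i - 1][j - 1] > prev_val:
                    prev_val, prev_state = grid[i - 1][j - 1], s
            M[i][j] = prev_val + sub[(qi, subject[j - 1])]
            ptr["M"][i][j] = prev_state
            # gap in subject: open from M or extend X
            open_x = M[i - 1][j] - gap_open - gap_extend
            ext_x = X[i - 1][j] - gap_extend
            if open_x >= ext_x:
                X[i][j], ptr["X"][i][j] = open_x, "M"
            else:
                X[i][j], ptr["X"][i][j] = ext_x, "X"
            # gap in query: open from M or extend Y
            open_y = M[i][j - 1] - gap_open - gap_extend
            ext_y = Y[i][j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i][j], ptr["Y"][i][j] = open_y, "M"
            else:
                Y[i][j], ptr["Y"][i][j] = ext_y, "Y"
            if M[i][j] > best:
                best, best_pos, best_state = M[i][j], (i, j), "M"
    if best_pos is None:
        return AlignmentHit(query, subject, 0.0, 0, 0)
    i, j = best_pos
    state = best_state
    length = matches = 0
    while state is not None:
        if state == "M":
            length += 1
            if query[i - 1] == subject[j - 1]:
                matches += 1
            state = ptr["M"][i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            length += 1
            state = ptr["X"][i][j]
            i -= 1
        else:
            length += 1
            state = ptr["Y"][i][j]
            j -= 1
    return AlignmentHit(query, subject, best, length, matches)


def percent_identity(
    query: str,
    viral_db: Sequence[str],
    mmax_as_percentage: bool = False,
    by_score: bool = False,
    **align_kwargs,
) -> float:
    """Best %I of a peptide against a viral peptide database.

    Per subject: %I = (matches / L_a) * (L_a / L_p) * 100 =
    matches / L_p * 100, with L_p the query length; the reported value
    is the maximum over subjects.  ``mmax_as_percentage`` reproduces
    the literal published formula where the identity term is itself a
    percentage (values then scale by a further 100).  ``by_score``
    selects the subject by alignment score instead of identity.
    """
    if not viral_db:
        raise ValueError("empty viral database")
    best = 0.0
    best_score = float("-inf")
    for subject in viral_db:
        hit = local_align(query, subject, **align_kwargs)
        if hit.length == 0:
            continue
        value = hit.matches / len(query) * 100.0
        if mmax_as_percentage:
            value *= 100.0
        if by_score:
            if hit.score > best_score:
                best_score, best = hit.score, value
        else:
            best = max(best, value)
    return best


def viral_homology_test(
    eremaps: Sequence[str],
    canonical_maps: Sequence[str],
    viral_db: Sequence[str],
    n_boot: int = 10000,
    seed: int | None = None,
    with_replacement: bool = False,
    **align_kwargs,
) -> dict:
    """Bootstrap test of viral homology of an ereMAP set.

    The observed statistic is the mean %I of the ereMAPs against the
    viral database.  Each of ``n_boot`` bootstrap sets draws
    ``len(eremaps)`` canonical peptides (without replacement within a
    set) and the p-value is the fraction of bootstrap means exceeding
    the observed mean.  A p of 0 is best read as < 1/n_boot.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    k = len(eremaps)
    if len(canonical_maps) < k:
        raise ValueError("canonical pool smaller than the ereMAP set")
    observed = float(
        np.mean([percent_identity(p, viral_db, **align_kwargs) for p in eremaps])
    )
    pool_pi = np.array(
        [percent_identity(p, viral_db, **align_kwargs) for p in canonical_maps]
    )
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = (
            rng.integers(0, len(pool_pi), size=k)
            if with_replacement
            else rng.choice(len(pool_pi), size=k, replace=False)
        )
        boot[b] = pool_pi[idx].mean()
    p = float((boot > observed).sum() / n_boot)
    return {
        "observed_mean": observed,
        "bootstrap_means": boot,
        "p_value": p,
        "n_boot": n_boot,
    }
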