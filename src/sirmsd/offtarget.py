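"""Seed-match off-target analysis of expression profiles.

Transcripts whose 3'UTR contains the exact DNA reverse complement of the
guide-strand seed (nucleotides 2–8 from the 5' end) are seed-matched (SM)
candidates for off-target repression.  After quality-flag filtering and
quantile normalization, the magnitude of the off-target effect is the
difference between the mean log2 fold change (treated vs mock) of SM and of
non-SM transcripts, with a two-sided Wilcoxon rank-sum test; cumulative
fold-change distributions and an MA table accompany the summary.

No G:U wobble and no mismatch tolerance: a transcript is SM iff the 7-mer
reverse complement occurs as an exact substring (U/T differences are
normalized away).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from .errors import QcError, SirmsdError

#: The six feature-extraction quality flags and their passing values.
QC_PASSING_VALUES: dict[str, int] = {
    "ControlType": 0,
    "gIsPosAndSignif": 1,
    "gIsFeatNonUnifOL": 0,
    "gIsWellAboveBG": 1,
    "gIsSaturated": 0,
    "gIsFeatPopnOL": 0,
}

#: RefSeq mRNA systematic-name pattern used by default.
DEFAULT_NAME_PATTERN = r"^NM_"


@dataclass
class TranscriptRecord:
    transcript_id: str
    utr3: str
    qc_flags: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.utr3 = normalize_dna(self.utr3)


def normalize_dna(seq: str) -> str:
    """Uppercase and re-encode U as T; validates the {A,C,G,T,N} alphabet."""
    seq = seq.strip().upper().replace("U", "T")
    if not re.fullmatch(r"[ACGTN]*", seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise SirmsdError(f"sequence contains non-nucleotide characters {bad}")
    return seq


@dataclass
class OffTargetSummary:
    mean_l2fc_sm: float
    mean_l2fc_nonsm: float
    difference: float  # SM − non-SM, log2 units
    p_wilcoxon: float
    n_sm: int
    n_nonsm: int


def seed_of(guide: str) -> str:
    """Seed heptamer: guide nucleotides 2–8 (1-based) as RNA."""
    guide = guide.strip().upper()
    if len(guide) < 8:
        raise SirmsdError(f"guide must be >= 8 nt, got {len(guide)}")
    return guide[1:8].replace("T", "U")


def seed_match_site(seed: str) -> str:
    """DNA reverse complement of the seed — the site searched for in 3'UTRs."""
    if len(seed) != 7:
        raise SirmsdError(f"seed must be a 7-mer, got {len(seed)} nt")
    return str(Seq(normalize_dna(seed)).reverse_complement())


def classify_sm(utrs: pd.Series | dict[str, str], seed: str) -> pd.Series:
    """Boolean SM flag per transcript: exact seed-complement substring in 3'UTR."""
    site = seed_match_site(seed)
    if isinstance(utrs, dict):
        utrs = pd.Series(utrs)
    return utrs.map(lambda u: site in normalize_dna(u)).astype(bool)


def qc_filter(table: pd.DataFrame,
              name_pattern: str = DEFAULT_NAME_PATTERN,
              name_column: str = "SystematicName") -> pd.DataFrame:
    """Rows surviving the six QC-flag conditions and the systematic-name pattern."""
    for flag in QC_PASSING_VALUES:
        if flag not in table.columns:
            raise QcError(f"missing QC flag column {flag!r}")
    if name_column not in table.columns:
        raise QcError(f"missing identifier column {name_column!r}")
    mask = pd.Series(True, index=table.index)
    for flag, passing in QC_PASSING_VALUES.items():
        mask &= table[flag] == passing
    mask &= table[name_column].astype(str).str.match(name_pattern)
    return table[mask].copy()


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean distribution.

    After normalization each column's sorted values equal the row-wise mean
    of the sorted input columns; within-column ranks are preserved, and tied
    values receive the mean of their tied quantile targets.
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise SirmsdError("expression intensities must be positive")
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = sps.rankdata(values[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks - 1.0, np.arange(n), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration for small tie-free samples (min group size <= 20),
    normal approximation with continuity correction otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def offtarget_magnitude(
    matrix: pd.DataFrame,
    sm_flags: pd.Series,
    treated_sample: str,
    mock_sample: str,
) -> tuple[OffTargetSummary, pd.DataFrame, pd.DataFrame]:
    """Off-target shift of SM vs non-SM transcripts.

    ``matrix`` is a (quantile-normalized) transcripts × samples intensity
    table.  Returns the summary plus a tidy cumulative-fraction table
    (columns ``group, l2fc, cumulative_fraction``) and an MA table (columns
    ``transcript_id, M, A, sm``) with M the log2 fold change treated/mock
    and A the average log10 intensity.
    """
    for col in (treated_sample, mock_sample):
        if col not in matrix.columns:
            raise SirmsdError(f"sample column {col!r} absent from matrix")
    sm = sm_flags.reindex(matrix.index)
    if sm.isna().any():
        raise SirmsdError("sm_flags must cover every transcript in the matrix")
    sm = sm.astype(bool)

    treated = matrix[treated_sample].to_numpy(dtype=float)
    mock = matrix[mock_sample].to_numpy(dtype=float)
    l2fc = np.log2(treated / mock)
    a_val = (np.log10(treated) + np.log10(mock)) / 2.0

    sm_vals = l2fc[sm.to_numpy()]
    nonsm_vals = l2fc[~sm.to_numpy()]
    if sm_vals.size == 0 or nonsm_vals.size == 0:
        raise SirmsdError("both SM and non-SM groups must be non-empty")

    summary = OffTargetSummary(
        mean_l2fc_sm=float(sm_vals.mean()),
        mean_l2fc_nonsm=float(nonsm_vals.mean()),
        difference=float(sm_vals.mean() - nonsm_vals.mean()),
        p_wilcoxon=rank_sum_test(sm_vals, nonsm_vals),
        n_sm=int(sm_vals.size),
        n_nonsm=int(nonsm_vals.size),
    )

    cum_frames = []
    for group, vals in (("SM", sm_vals), ("non-SM", nonsm_vals)):
        order = np.sort(vals)
        cum_frames.append(pd.DataFrame({
            "group": group,
            "l2fc": order,
            "cumulative_fraction": np.arange(1, order.size + 1) / order.size,
        }))
    cumulative = pd.concat(cum_frames, ignore_index=True)

    ma = pd.DataFrame({
        "transcript_id": matrix.index,
        "M": l2fc,
        "A": a_val,
        "sm": sm.to_numpy(),
    })
    return summary, cumulative, ma
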