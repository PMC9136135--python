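"""Differential motif prevalence and two-proportion Z-tests.

Prevalence here is presence-based: a motif's count in a cohort is the
number of proteins containing at least one occurrence, never the number
of occurrences. Differential motifs are those whose positive-set
prevalence exceeds the negative-set prevalence by at least a relative
factor (default 1.3, i.e. occurring at least 30% more often among
positive-set proteins), ranked by the prevalence difference.

The class-level significance test is the textbook pooled two-proportion
Z-test, two-sided, without continuity correction:

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)),
    phat = (x1 + x2) / (n1 + n2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

from scipy.stats import norm

from .motif_engine import (
    enumerate_motifs,
    hits_of_class,
    sequence_kmer_set,
)
from .sequence_io import ProteinRecord

LN10 = math.log(10.0)


class DegenerateTestError(ValueError):
    """Z statistic undefined: pooled proportion is 0 or 1."""


@dataclass(frozen=True)
class TestResult:
    """Pooled two-proportion Z-test outcome.

    ``log10_p`` is computed from the normal log-survival function so it
    stays finite far into the tail where ``p_two_sided`` underflows.
    """

    z: float
    p_two_sided: float
    log10_p: float


@dataclass
class EnrichmentRow:
    """Per-motif (or per-class) prevalence contrast between two cohorts."""

    motif_or_class: str
    n_pos: int
    N_pos: int
    n_neg: int
    N_neg: int
    f_pos: float
    f_neg: float
    ratio: float  # inf when f_neg == 0 < f_pos
    diff: float
    z: float
    p: float
    log10_p: float


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion Z-test (two-sided).

    Raises :class:`DegenerateTestError` when the pooled proportion is 0
    or 1, where the statistic is undefined.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateTestError(
            f"pooled proportion {pooled} leaves zero variance"
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    # two-sided p = 2 * P(Z > |z|); logsf avoids underflow in the far tail
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    log10_p = min(0.0, (math.log(2.0) + norm.logsf(abs(z))) / LN10)
    return TestResult(z=z, p_two_sided=p, log10_p=log10_p)


def _safe_ztest(x1: int, n1: int, x2: int, n2: int):
    """Z-test returning NaNs (p = 1) where the test is degenerate."""
    try:
        t = two_prop_ztest(x1, n1, x2, n2)
        return t.z, t.p_two_sided, t.log10_p
    except DegenerateTestError:
        return float("nan"), 1.0, 0.0


def presence_table(
    records: Sequence[ProteinRecord], k: int, mirror: bool = False
) -> Dict[str, int]:
    """Per-motif protein counts: how many records contain each k-mer.

    Every enumerated motif appears as a key (zero counts included); each
    protein contributes at most 1 to each motif's count. With ``mirror``
    the keys are the 4200-style canonical forms.
    """
    if not records:
        raise ValueError("empty record list")
    counts = {m: 0 for m in enumerate_motifs(k, collapse_mirror=mirror)}
    for rec in records:
        for kmer in sequence_kmer_set(rec.sequence, k, mirror=mirror):
            counts[kmer] += 1
    return counts


def _build_row(name, n_pos, N_pos, n_neg, N_neg) -> EnrichmentRow:
    f_pos = n_pos / N_pos
    f_neg = n_neg / N_neg
    if f_neg > 0:
        ratio = f_pos / f_neg
    else:
        ratio = math.inf if f_pos > 0 else float("nan")
    z, p, lp = _safe_ztest(n_pos, N_pos, n_neg, N_neg)
    return EnrichmentRow(
        motif_or_class=name,
        n_pos=n_pos,
        N_pos=N_pos,
        n_neg=n_neg,
        N_neg=N_neg,
        f_pos=f_pos,
        f_neg=f_neg,
        ratio=ratio,
        diff=f_pos - f_neg,
        z=z,
        p=p,
        log10_p=lp,
    )


def differential_motifs(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    k: int,
    min_ratio: float = 1.3,
    top_n: int = 10,
    mirror: bool = False,
) -> List[EnrichmentRow]:
    """Top differentially prevalent k-mers under the relative-ratio constraint.

    A motif qualifies when ``f_pos >= min_ratio * f_neg`` and ``f_pos > 0``
    (motifs absent from the negative set but present in the positive set
    qualify with infinite ratio). Qualifying motifs are ranked by
    prevalence difference ``f_pos - f_neg`` descending, ties broken
    lexicographically, and the first ``top_n`` returned.
    """
    if not pos or not neg:
        raise ValueError("both cohorts must be non-empty")
    pos_counts = presence_table(pos, k, mirror=mirror)
    neg_counts = presence_table(neg, k, mirror=mirror)
    N_pos, N_neg = len(pos), len(neg)
    rows = []
    for motif in pos_counts:
        n_pos = pos_counts[motif]
        n_neg = neg_counts[motif]
        f_pos = n_pos / N_pos
        f_neg = n_neg / N_neg
        if f_pos <= 0 or f_pos < min_ratio * f_neg:
            continue
        rows.append(_build_row(motif, n_pos, N_pos, n_neg, N_neg))
    rows.sort(key=lambda r: (-r.diff, r.motif_or_class))
    return rows[:top_n]


def class_presence_count(
    records: Sequence[ProteinRecord], class_def
) -> int:
    """Number of records with >= 1 hit of any member of the class."""
    return sum(
        1 for rec in records if hits_of_class(rec.sequence, class_def)
    )


def class_sty_enrichment(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    class_def,
    window: int = 3,
    class_name: str | None = None,
) -> EnrichmentRow:
    """Prevalence contrast of class hits with a phosphorylatable flank.

    A protein counts once if at least one of its class hits has an S, T
    or Y residue within ``window`` residues of either flank (residues
    inside the hit excluded).
    """
    from .proximity import sty_near_any

    if not pos or not neg:
        raise ValueError("both cohorts must be non-empty")
    name = class_name or f"{class_def}+STY"

    def count(records):
        return sum(
            1
            for rec in records
            if sty_near_any(
                rec.sequence, hits_of_class(rec.sequence, class_def), window
            )
        )

    return _build_row(name, count(pos), len(pos), count(neg), len(neg))


def class_enrichment(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    class_def,
    class_name: str | None = None,
) -> EnrichmentRow:
    """Prevalence contrast of a motif class (e.g. triacidic, KKX).

    A protein counts once if it contains at least one hit of any member
    motif or pattern of the class. The row carries the counts, both
    prevalences, and their pooled two-proportion Z-test.
    """
    if not pos or not neg:
        raise ValueError("both cohorts must be non-empty")
    name = class_name or (
        class_def if isinstance(class_def, str) else "+".join(map(str, class_def))
    )
    n_pos = class_presence_count(pos, class_def)
    n_neg = class_presence_count(neg, class_def)
    return _build_row(name, n_pos, len(pos), n_neg, len(neg))


#: fixed column order of the enrichment TSV
ENRICHMENT_COLUMNS = [
    "motif", "n_pos", "N_pos", "n_neg", "N_neg",
    "f_pos", "f_neg", "ratio", "diff", "z", "p", "log10_p",
]


def rows_to_dataframe(rows: Sequence[EnrichmentRow], bonferroni_m: int | None = None):
    """Enrichment rows as a DataFrame in the fixed column order.

    ``bonferroni_m`` appends a Bonferroni-adjusted p column over the given
    number of tested motifs (opt-in; the default report is uncorrected).
    """
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "motif": r.motif_or_class,
                "n_pos": r.n_pos,
                "N_pos": r.N_pos,
                "n_neg": r.n_neg,
                "N_neg": r.N_neg,
                "f_pos": r.f_pos,
                "f_neg": r.f_neg,
                "ratio": r.ratio,
                "diff": r.diff,
                "z": r.z,
                "p": r.p,
                "log10_p": r.log10_p,
            }
            for r in rows
        ],
        columns=ENRICHMENT_COLUMNS,
    )
    if bonferroni_m:
        df["p_bonferroni"] = (df["p"] * bonferroni_m).clip(upper=1.0)
    return df
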