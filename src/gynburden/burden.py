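"""Per-gene carrier-burden statistics versus a control population.

Carriers are unique heterozygotes with at least one pathogenic or likely
pathogenic variant in a gene; each gene is compared to the control
population in a 2x2 table with a two-tailed Pearson chi-square test
(df = 1, no continuity correction by default) and a Woolf log-normal 95%
confidence interval around the odds ratio. Rows with zero study carriers,
or any zero cell, report NA statistics. Display rounding is half-up:
2 decimals for percentages and odds ratios, 3 for the chi-square statistic.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from math import log, exp, sqrt
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .models import BurdenRow, ClassifiedVariant, CohortSummary, ControlSummary


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's round()."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_percent(count: int, n: int) -> float:
    """Carrier frequency as a percentage, half-up to 2 decimals."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not (0 <= count <= n):
        raise ValueError(f"count {count} outside [0, {n}]")
    return round_half_up(100.0 * count / n, 2)


def control_count_from_freq(freq_percent: float, n: int) -> int:
    """Reconstruct a carrier count from a printed percentage (half-up)."""
    if not (0.0 <= freq_percent <= 100.0):
        raise ValueError("frequency percent must lie in [0, 100]")
    return int(Decimal(repr(freq_percent)) / 100 * n + Decimal("0.5"))


def chi_square_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> Optional[tuple[float, float]]:
    """Pearson chi-square on [[a, b], [c, d]], two-tailed, df = 1.

    Returns None when a margin is zero (the statistic is undefined).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return None
    stat, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=yates)
    return float(stat), float(p)


def odds_ratio_ci(
    a: int, b: int, c: int, d: int, z: float = 1.96
) -> Optional[tuple[float, float, float]]:
    """Odds ratio (ad/bc) with the Woolf log-normal 95% CI.

    Any zero cell yields None (NA), matching tables that print NA for genes
    with no carriers.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        return None
    or_ = (a * d) / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, exp(log(or_) - z * se), exp(log(or_) + z * se)


def count_carriers(
    classified: Sequence[ClassifiedVariant],
    carrier_ids: Mapping[str, Iterable[str]],
    n_individuals: int,
    genes: Sequence[str],
) -> CohortSummary:
    """Unique-heterozygote P/LP carriers per gene.

    ``carrier_ids`` maps variant_id to the individuals carrying it; an
    individual with two P/LP variants in one gene counts once for that gene.
    """
    known = {cv.variant_id for cv in classified}
    unknown = set(carrier_ids) - known
    if unknown:
        raise ValueError(
            "genotypes reference unknown variant_id(s): "
            + ", ".join(sorted(unknown)[:5]))
    per_gene_people: dict[str, set] = {g: set() for g in genes}
    per_gene_variants: dict[str, int] = {g: 0 for g in genes}
    for cv in classified:
        if not cv.is_plp:
            continue
        if cv.gene not in per_gene_people:
            raise ValueError(f"classified variant in non-panel gene {cv.gene!r}")
        per_gene_variants[cv.gene] += 1
        per_gene_people[cv.gene].update(carrier_ids.get(cv.variant_id, ()))
    return CohortSummary(
        n_individuals=n_individuals,
        per_gene_carriers={g: len(p) for g, p in per_gene_people.items()},
        per_gene_variants=per_gene_variants,
    )


def _row(gene: str, a: Optional[int], n_study: int,
         c: Optional[int], c_freq: Optional[float], n_control: int,
         yates: bool) -> BurdenRow:
    study_freq = prevalence_percent(a, n_study) if a is not None else None
    if c is None and c_freq is not None:
        c = control_count_from_freq(c_freq, n_control)
    control_freq = (round_half_up(c_freq, 2) if c_freq is not None
                    else prevalence_percent(c, n_control) if c is not None else None)
    if a is None or c is None or a == 0:
        return BurdenRow(gene, a, study_freq, c, control_freq,
                         None, None, None, None, None)
    b, d = n_study - a, n_control - c
    orci = odds_ratio_ci(a, b, c, d)
    chi = chi_square_2x2(a, b, c, d, yates=yates)
    return BurdenRow(
        gene=gene, study_count=a, study_freq=study_freq,
        control_count=c, control_freq=control_freq,
        odds_ratio=round_half_up(orci[0], 2) if orci else None,
        ci_low=round_half_up(orci[1], 2) if orci else None,
        ci_high=round_half_up(orci[2], 2) if orci else None,
        chi2=round_half_up(chi[0], 3) if chi else None,
        p_value=chi[1] if chi else None,
    )


def build_burden_table(
    study: CohortSummary,
    control: ControlSummary,
    genes: Sequence[str],
    yates: bool = False,
) -> list[BurdenRow]:
    """One row per panel gene plus a Sum row.

    The Sum row compares total carriers (summed over genes, so an individual
    carrying P/LP variants in two genes is counted twice, matching the
    per-gene arithmetic) against total control carriers.
    """
    extra = set(control.per_gene_count) - set(genes)
    if extra:
        raise ValueError(
            "control summary contains non-panel gene(s): " + ", ".join(sorted(extra)))
    rows = []
    total_control = 0
    control_known = True
    for gene in genes:
        a = study.per_gene_carriers.get(gene, 0)
        c = control.per_gene_count.get(gene)
        c_freq = control.per_gene_freq_percent.get(gene)
        if c is None and c_freq is not None:
            c = control_count_from_freq(c_freq, control.n_individuals)
        if c is None:
            control_known = control_known and a == 0  # NA control only tolerable for NA rows
        else:
            total_control += c
        rows.append(_row(gene, a, study.n_individuals, c, c_freq,
                         control.n_individuals, yates))
    rows.append(_row("Sum", study.total_carriers, study.n_individuals,
                     total_control if control_known else None, None,
                     control.n_individuals, yates))
    return rows
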