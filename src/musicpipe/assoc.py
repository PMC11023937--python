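"""Association of cell-type-specific eQTL-target pairs with contacts.

A DNA-DNA contact *supports* an eQTL-target pair when one end overlaps
the variant position (>= 1 bp) and the other end overlaps the target
promoter (TSS +/- 2.5 kb, closed); both end assignments are tried.
Supporting contacts are cross-tabulated by (contact cell type x eQTL
cell type) into a 6x6 table for a global Pearson chi-square test
(df = 25), which is reduced to per-type 2x2 tables with odds ratios and
the Wald 95% CI exp(log(OR) +/- 1.96 * SE), SE = sqrt(1/a+1/b+1/c+1/d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PROMOTER_FLANK = 2_500
EQTL_MAX_P = 1e-4


@dataclass(frozen=True)
class EqtlPair:
    """One cell-type-specific eQTL-target gene pair.

    ``pos`` is 0-based internally (input tables are 1-based); the
    variant is treated as a 1 bp interval.  ``cell_types`` is the set
    of types (from the fixed panel) in which the eQTL affects the
    target.
    """

    chrom: str
    pos: int
    gene: str
    tss: int
    cell_types: frozenset[str]
    p_value: float = 0.0

    @property
    def promoter(self) -> tuple[int, int]:
        """Closed promoter interval [TSS - 2500, TSS + 2500]."""
        return (self.tss - PROMOTER_FLANK, self.tss + PROMOTER_FLANK)


@dataclass(frozen=True)
class ContactRecord:
    """A DNA-DNA contact end pair with its cell-of-origin type."""

    chrom: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    cell_type: str


def load_eqtl_table(path, max_p: float = EQTL_MAX_P) -> list[EqtlPair]:
    """Read a TSV of (chrom, pos[1-based], gene, tss[1-based], cell_types, p)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        if row.p > max_p:
            continue
        out.append(
            EqtlPair(
                chrom=row.chrom,
                pos=int(row.pos) - 1,
                gene=row.gene,
                tss=int(row.tss) - 1,
                cell_types=frozenset(str(row.cell_types).split(",")),
                p_value=float(row.p),
            )
        )
    return out


def _overlaps_point(start: int, end: int, pos: int) -> bool:
    return start <= pos < end


def _overlaps_closed(start: int, end: int, lo: int, hi: int) -> bool:
    return start <= hi and end - 1 >= lo


def supports(contact: ContactRecord, pair: EqtlPair) -> bool:
    """Does this contact link the variant to the target promoter?"""
    if contact.chrom != pair.chrom:
        return False
    lo, hi = pair.promoter
    a_var = _overlaps_point(contact.start_a, contact.end_a, pair.pos)
    b_var = _overlaps_point(contact.start_b, contact.end_b, pair.pos)
    a_prom = _overlaps_closed(contact.start_a, contact.end_a, lo, hi)
    b_prom = _overlaps_closed(contact.start_b, contact.end_b, lo, hi)
    return (a_var and b_prom) or (b_var and a_prom)


def supporting_contacts(
    contacts: list[ContactRecord], pairs: list[EqtlPair]
) -> list[tuple[int, int]]:
    """All (contact index, pair index) support links."""
    out = []
    for i, c in enumerate(contacts):
        for j, p in enumerate(pairs):
            if supports(c, p):
                out.append((i, j))
    return out


@dataclass
class SupportTable:
    """Contingency counts: rows = contact cell type, cols = eQTL cell type."""

    table: pd.DataFrame
    cts_only: bool = False

    @property
    def df(self) -> int:
        r, c = self.table.shape
        return (r - 1) * (c - 1)


def build_support_table(
    contacts: list[ContactRecord],
    pairs: list[EqtlPair],
    cell_types: list[str],
    cts_only: bool = True,
) -> SupportTable:
    """Cross-tabulate support links by contact and eQTL cell type.

    ``cts_only`` restricts to pairs exclusive to a single cell type
    (each link then increments exactly one cell); otherwise a link
    increments every cell type the pair is active in.
    """
    tab = pd.DataFrame(0, index=cell_types, columns=cell_types)
    for i, j in supporting_contacts(contacts, pairs):
        c, p = contacts[i], pairs[j]
        if cts_only and len(p.cell_types) != 1:
            continue
        if c.cell_type not in cell_types:
            continue
        for t in p.cell_types:
            if t in cell_types:
                tab.loc[c.cell_type, t] += 1
    return SupportTable(table=tab, cts_only=cts_only)


@dataclass
class OddsRatioResult:
    cell_type: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


def odds_ratio_2x2(a: float, b: float, c: float, d: float, cell_type: str = "") -> OddsRatioResult:
    """OR = ad/bc with the Wald CI exp(log(OR) +/- 1.96 * SELOR)."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        cell_type=cell_type,
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - 1.96 * se)),
        ci_high=float(np.exp(np.log(or_) + 1.96 * se)),
        corrected=corrected,
    )


def chisq_and_or(support: SupportTable) -> dict:
    """Global Pearson chi-square on the full table + per-type 2x2 ORs.

    For type t the 2x2 reduction is
    ``[[n(t,t), n(t, not t)], [n(not t, t), n(not t, not t)]]``.
    Warns (in the result) when any expected count is below 5; refuses
    an empty table.
    """
    tab = support.table.to_numpy(dtype=float)
    total = tab.sum()
    if total == 0:
        raise ValueError("empty support table; test refused")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    per_type = []
    for t in support.table.index:
        a = support.table.loc[t, t]
        b = support.table.loc[t].sum() - a
        c = support.table[t].sum() - a
        d = total - a - b - c
        per_type.append(odds_ratio_2x2(a, b, c, d, cell_type=t))
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "low_expected": bool((expected < 5).any()),
        "per_type": per_type,
    }


# ---------------------------------------------------------- simulators

def simulate_enriched_2x2(
    true_or: float,
    n_per_arm: int,
    seed: int,
    baseline_p: float = 0.2,
) -> tuple[np.ndarray, float]:
    """A 2x2 support table with a planted odds ratio.

    Contacts of the focal type support same-type pairs with probability
    p1 where odds(p1) = true_or * odds(baseline_p); other contacts use
    ``baseline_p``.  Returns (table [[a, b], [c, d]], planted OR).
    """
    rng = np.random.default_rng(seed)
    odds1 = true_or * baseline_p / (1 - baseline_p)
    p1 = odds1 / (1 + odds1)
    a = rng.binomial(n_per_arm, p1)
    c = rng.binomial(n_per_arm, baseline_p)
    return np.array([[a, n_per_arm - a], [c, n_per_arm - c]], dtype=float), true_or


def simulate_null_table(
    n_contacts: int, n_types: int, seed: int
) -> pd.DataFrame:
    """A support table with independent contact and eQTL cell types."""
    rng = np.random.default_rng(seed)
    types = [f"t{i}" for i in range(n_types)]
    rows = rng.integers(0, n_types, size=n_contacts)
    cols = rng.integers(0, n_types, size=n_contacts)
    counts = np.zeros((n_types, n_types), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    return pd.DataFrame(counts, index=types, columns=types)


def or_ci_coverage(
    true_or: float,
    n_replicates: int,
    seed: int,
    n_per_arm: int = 1_000,
    baseline_p: float = 0.2,
) -> float:
    """Fraction of replicates whose 95% Wald CI covers the planted OR."""
    hits = 0
    for i in range(n_replicates):
        tab, truth = simulate_enriched_2x2(true_or, n_per_arm, seed + i, baseline_p)
        res = odds_ratio_2x2(*tab.ravel())
        if res.ci_low <= truth <= res.ci_high:
            hits += 1
    return hits / n_replicates


def null_chisq_pvalues(
    n_replicates: int, seed: int, n_contacts: int = 2_000, n_types: int = 6
) -> np.ndarray:
    """Global-test p-values under independence (should be ~uniform)."""
    ps = np.empty(n_replicates)
    for i in range(n_replicates):
        tab = simulate_null_table(n_contacts, n_types, seed + i)
        chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        ps[i] = p
    return ps
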