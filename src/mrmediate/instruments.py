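"""Instrumental-variable selection for two-sample MR.

Implements the three classical requirements on instruments: association
strength (genome-wide p-value threshold and F statistic >= 10), mutual
independence (greedy LD clumping at r² <= 0.001 in a 10,000 kb window), and
absence of known confounder associations (screened against a local
annotation table of SNP-trait lookups).

The instrument-strength statistics follow the standard summary-data forms

    R² = 2·β² / (2·β² + 2·N·se²)        (variance explained by one SNP)
    F  = (N − 2) · R² / (1 − R²)        (single-instrument F statistic)

which reduce to R² = z²/(z²+N) and F = (N−2)·β²/(N·se²) with z = β/se.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SnpAssociation

__all__ = [
    "InstrumentStrength",
    "LdTable",
    "ConfounderTable",
    "variance_explained",
    "f_statistic",
    "clump",
    "select_instruments",
]


def _check_domain(beta, se, n) -> None:
    se = np.asarray(se, float)
    n = np.asarray(n)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("se must be positive and finite")
    if np.any(n < 3):
        raise ValueError("sample size must be >= 3")


def variance_explained(beta, se, n):
    """Variance in the exposure explained by one SNP, in [0, 1).

    Accepts scalars or arrays (broadcast).
    """
    _check_domain(beta, se, n)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    n = np.asarray(n, float)
    r2 = 2 * beta**2 / (2 * beta**2 + 2 * n * se**2)
    return r2 if r2.ndim else float(r2)


def f_statistic(beta, se, n):
    """Single-instrument F statistic, (N−2)·R²/(1−R²)."""
    _check_domain(beta, se, n)
    n = np.asarray(n, float)
    r2 = np.asarray(variance_explained(beta, se, n))
    f = (n - 2) * r2 / (1 - r2)
    return f if f.ndim else float(f)


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP instrument-strength summary."""

    snp_id: str
    r2: float
    f_stat: float

    @classmethod
    def from_association(cls, rec: SnpAssociation) -> "InstrumentStrength":
        return cls(rec.snp_id, variance_explained(rec.beta, rec.se, rec.n), f_statistic(rec.beta, rec.se, rec.n))


@dataclass
class LdTable:
    """Pairwise LD (r²) lookups between SNPs.

    ``entries`` maps an unordered id pair (stored sorted) to r²; absent pairs
    are treated as r² = 0 (unlinked), and r²(x, x) = 1.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError("r² must lie in [0, 1]")
        self.entries[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.entries.get(self._key(a, b), 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
            table.set_r2(str(a), str(b), float(r2))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted((a, b, r2) for (a, b), r2 in self.entries.items())
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)


@dataclass
class ConfounderTable:
    """Local SNP→trait annotation table emulating a PhenoScanner-style lookup."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp", "trait", "pval"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfounderTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"snp": str, "trait": str}))

    def confounded_snps(
        self, traits: Iterable[str] | None = None, p_threshold: float = 5e-8
    ) -> set[str]:
        """SNPs associated (p < threshold) with any of the given confounder traits.

        With ``traits=None`` every annotated trait counts as a confounder.
        """
        df = self.rows
        if df.empty:
            return set()
        mask = df["pval"].astype(float) < p_threshold
        if traits is not None:
            mask &= df["trait"].isin(set(traits))
        return set(df.loc[mask, "snp"].astype(str))


def clump(
    candidates: Sequence[SnpAssociation],
    ld: LdTable,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> list[SnpAssociation]:
    """Greedy LD clumping.

    Repeatedly keeps the remaining SNP with the smallest p-value (ties broken
    by chromosome then position) and removes all other SNPs on the same
    chromosome within ``window_kb`` whose r² with it exceeds ``r2_max``.
    Missing LD entries count as r² = 0.  Kept SNPs are returned in their
    original input order.
    """
    if not candidates:
        return []
    window_bp = window_kb * 1_000
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].pval, candidates[i].chrom, candidates[i].pos))
    alive = [True] * len(candidates)
    kept_idx: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        kept_idx.append(i)
        lead = candidates[i]
        for j in range(len(candidates)):
            if j == i or not alive[j]:
                continue
            other = candidates[j]
            if other.chrom != lead.chrom:
                continue
            if abs(other.pos - lead.pos) > window_bp:
                continue
            if ld.r2(lead.snp_id, other.snp_id) > r2_max:
                alive[j] = False
        alive[i] = False  # processed
    kept_idx.sort()
    return [candidates[i] for i in kept_idx]


def select_instruments(
    stats: Sequence[SnpAssociation],
    ld: LdTable,
    confounders: ConfounderTable | None = None,
    p_threshold: float = 5e-8,
    f_min: float = 10.0,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    confounder_traits: Iterable[str] | None = None,
    confounder_p: float = 5e-8,
) -> tuple[list[SnpAssociation], pd.DataFrame]:
    """Full instrument-selection cascade with a per-SNP fate report.

    Filters are applied in order: p-value threshold → LD clumping → F ≥ f_min
    → confounder screening, so that clumping sees the complete significant
    panel.  The report's fates (``kept``, ``removed_pvalue``,
    ``removed_clump``, ``removed_weak_f``, ``removed_confounder``) partition
    the input.  Zero survivors is a legitimate outcome, not an error; the
    report carries the reason counts.
    """
    fates: dict[str, str] = {}
    significant = []
    for rec in stats:
        if rec.pval < p_threshold:
            significant.append(rec)
        else:
            fates[rec.snp_id] = "removed_pvalue"

    clumped = clump(significant, ld, r2_max=clump_r2, window_kb=clump_kb)
    clumped_ids = {r.snp_id for r in clumped}
    for rec in significant:
        if rec.snp_id not in clumped_ids:
            fates[rec.snp_id] = "removed_clump"

    strong = []
    for rec in clumped:
        if f_statistic(rec.beta, rec.se, rec.n) >= f_min:
            strong.append(rec)
        else:
            fates[rec.snp_id] = "removed_weak_f"

    bad = confounders.confounded_snps(confounder_traits, confounder_p) if confounders is not None else set()
    instruments = []
    for rec in strong:
        if rec.snp_id in bad:
            fates[rec.snp_id] = "removed_confounder"
        else:
            fates[rec.snp_id] = "kept"
            instruments.append(rec)

    report = pd.DataFrame({"snp_id": [r.snp_id for r in stats], "fate": [fates[r.snp_id] for r in stats]})
    return instruments, report
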