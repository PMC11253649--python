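"""Reading, validation and allele harmonization of GWAS summary statistics.

The canonical on-disk dialect is a tab-delimited table with header
``snp  chr  pos  ea  oa  eaf  beta  se  pval  n`` (one SNP per line,
gzip-transparent).  Other dialects are adapted with a user-supplied column
map.  Betas are per-allele effects on the trait: log-odds for binary
outcomes, SD units for continuous traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import SummaryStatsFormatError

__all__ = [
    "SnpAssociation",
    "HarmonizedInstrumentSet",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
]

VALID_ALLELES = frozenset("ACGT")
#: allele pairs whose complement equals their swap — strand-ambiguous
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})
#: canonical column order of the summary-statistics TSV
CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> str | None:
        """Return a reason string if any invariant is violated, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not np.isfinite(self.beta):
            return "non_numeric_beta"
        if not np.isfinite(self.se) or self.se <= 0:
            return "non_positive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf_out_of_range"
        if self.n < 2:
            return "sample_size_too_small"
        if self.pos < 1:
            return "non_positive_position"
        return None

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS


def _coerce_row(row: Mapping[str, object]) -> SnpAssociation:
    eaf = row.get("eaf")
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        eaf_val: float | None = None
    else:
        eaf_val = float(eaf)  # type: ignore[arg-type]
    return SnpAssociation(
        snp_id=str(row["snp"]),
        chrom=str(row["chr"]),
        pos=int(row["pos"]),
        effect_allele=str(row["ea"]).upper(),
        other_allele=str(row["oa"]).upper(),
        eaf=eaf_val,
        beta=float(row["beta"]),  # type: ignore[arg-type]
        se=float(row["se"]),  # type: ignore[arg-type]
        pval=float(row["pval"]),  # type: ignore[arg-type]
        n=int(row["n"]),  # type: ignore[arg-type]
    )


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SnpAssociation], pd.DataFrame]:
    """Read and validate a summary-statistics table.

    Parameters
    ----------
    path
        Tab-delimited file, optionally gzip-compressed.
    column_map
        Maps canonical names (``snp``, ``chr``, ...) to the file's actual
        header names, for non-canonical dialects.

    Returns
    -------
    records, rejects
        Validated records, and a per-row rejection report with columns
        ``row`` (1-based data-row number), ``snp`` and ``reason``.  Rows
        failing any invariant, and every row of a duplicated SNP id, are
        rejected rather than silently repaired.

    Raises
    ------
    SummaryStatsFormatError
        If a mandatory column is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    mandatory = [c for c in CANONICAL_COLUMNS if c != "eaf"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SummaryStatsFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    records: list[SnpAssociation] = []
    rows: list[int] = []
    reject_rows: list[tuple[int, str, str]] = []
    for i, raw in enumerate(df.to_dict("records"), start=1):
        snp = str(raw.get("snp", ""))
        try:
            rec = _coerce_row(_numericize(raw))
        except (ValueError, TypeError, KeyError):
            reject_rows.append((i, snp, "unparseable_row"))
            continue
        reason = rec.validate()
        if reason is not None:
            reject_rows.append((i, snp, reason))
            continue
        records.append(rec)
        rows.append(i)

    # duplicated ids: reject every occurrence rather than guessing which is right
    ids = pd.Series([r.snp_id for r in records])
    dup_mask = ids.duplicated(keep=False).to_numpy()
    if dup_mask.any():
        for keep, rec, row in zip(~dup_mask, records, rows):
            if not keep:
                reject_rows.append((row, rec.snp_id, "duplicate_id"))
        records = [r for keep, r in zip(~dup_mask, records) if keep]

    rejects = pd.DataFrame(reject_rows, columns=["row", "snp", "reason"]).sort_values("row").reset_index(drop=True)
    return records, rejects


def _numericize(raw: Mapping[str, object]) -> dict:
    out = dict(raw)
    for key in ("pos", "n"):
        out[key] = int(float(str(out[key])))
    for key in ("beta", "se", "pval"):
        out[key] = float(str(out[key]))
    eaf = out.get("eaf")
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)) or str(eaf).upper() in ("NA", "NAN", ""):
        out["eaf"] = np.nan
    else:
        out["eaf"] = float(str(eaf))
    return out


def records_to_frame(records: Sequence[SnpAssociation]) -> pd.DataFrame:
    """Canonical DataFrame view of a record list (column order of the TSV)."""
    return pd.DataFrame(
        {
            "snp": [r.snp_id for r in records],
            "chr": [r.chrom for r in records],
            "pos": pd.array([r.pos for r in records], dtype="int64"),
            "ea": [r.effect_allele for r in records],
            "oa": [r.other_allele for r in records],
            "eaf": [np.nan if r.eaf is None else r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pval for r in records],
            "n": pd.array([r.n for r in records], dtype="int64"),
        }
    )


def write_summary_stats(records: Sequence[SnpAssociation], path: str | Path) -> None:
    """Write records as canonical TSV; floats use shortest round-trip repr."""
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned exposure/outcome betas for a selected instrument panel.

    ``records`` has one row per exposure SNP with columns ``snp_id``,
    ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out``, ``action``; the
    actions partition the input (kept / flipped / dropped_*).  Only kept and
    flipped rows carry outcome values.
    """

    exposure_id: str
    outcome_id: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    KEPT_ACTIONS = ("kept", "flipped")

    @property
    def kept(self) -> pd.DataFrame:
        if self.records.empty:
            return self.records
        return self.records[self.records["action"].isin(self.KEPT_ACTIONS)]

    @property
    def n_snp(self) -> int:
        return len(self.kept)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) over kept instruments."""
        k = self.kept
        return (
            k["beta_exp"].to_numpy(float),
            k["se_exp"].to_numpy(float),
            k["beta_out"].to_numpy(float),
            k["se_out"].to_numpy(float),
        )

    @property
    def snp_ids(self) -> list[str]:
        return self.kept["snp_id"].tolist()

    def subset(self, keep_snps: Iterable[str]) -> "HarmonizedInstrumentSet":
        """A new set restricted to the given kept SNP ids (dropped rows retained)."""
        keep = set(keep_snps)
        mask = ~self.records["action"].isin(self.KEPT_ACTIONS) | self.records["snp_id"].isin(keep)
        return HarmonizedInstrumentSet(self.exposure_id, self.outcome_id, self.records[mask].reset_index(drop=True))


def _orientation(exp: SnpAssociation, out: SnpAssociation) -> str:
    """How the outcome record's alleles relate to the exposure's.

    Returns 'same', 'swapped', 'same_flipped_strand', 'swapped_flipped_strand'
    or 'incompatible'.  Strand flips are recognised by complementing.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return "same"
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return "swapped"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (out.effect_allele, out.other_allele) == (cea, coa):
        return "same_flipped_strand"
    if (out.effect_allele, out.other_allele) == (coa, cea):
        return "swapped_flipped_strand"
    return "incompatible"


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindromic_policy: str = "drop",
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    eaf_ambiguity_band: float = 0.42,
) -> HarmonizedInstrumentSet:
    """Align outcome betas to the exposure's effect alleles.

    For each exposure SNP found in the outcome panel: matching allele order is
    kept as-is; swapped order flips the sign of the outcome beta.  Palindromic
    SNPs (A/T, C/G) are strand-ambiguous and are dropped under the default
    policy; under ``palindromic_policy="infer"`` they are retained when both
    panels report an effect-allele frequency outside the ambiguity band
    (< ``eaf_ambiguity_band`` or > 1 − band on both sides), oriented so the
    minor allele agrees.  Exposure SNPs absent from the outcome are recorded
    ``dropped_missing``; incompatible allele sets ``dropped_incompatible``.

    An empty intersection yields an empty (not erroneous) set.
    """
    if palindromic_policy not in ("drop", "infer"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")
    if not len(exposure) or not len(outcome):
        raise ValueError("exposure and outcome panels must be non-empty")
    out_by_id = {r.snp_id: r for r in outcome}

    rows = []
    for e in exposure:
        o = out_by_id.get(e.snp_id)
        row = {
            "snp_id": e.snp_id,
            "beta_exp": e.beta,
            "se_exp": e.se,
            "beta_out": np.nan,
            "se_out": np.nan,
            "action": "dropped_missing",
        }
        if o is not None:
            if e.is_palindromic:
                action, beta_out = _harmonize_palindromic(e, o, palindromic_policy, eaf_ambiguity_band)
            else:
                orient = _orientation(e, o)
                if orient in ("same", "same_flipped_strand"):
                    action, beta_out = "kept", o.beta
                elif orient in ("swapped", "swapped_flipped_strand"):
                    action, beta_out = "flipped", -o.beta
                else:
                    action, beta_out = "dropped_incompatible", np.nan
            row["action"] = action
            if action in HarmonizedInstrumentSet.KEPT_ACTIONS:
                row["beta_out"] = beta_out
                row["se_out"] = o.se
        rows.append(row)
    records = pd.DataFrame(rows, columns=["snp_id", "beta_exp", "se_exp", "beta_out", "se_out", "action"])
    return HarmonizedInstrumentSet(exposure_id, outcome_id, records)


def _harmonize_palindromic(
    e: SnpAssociation, o: SnpAssociation, policy: str, band: float
) -> tuple[str, float]:
    if policy == "drop":
        return "dropped_palindromic", np.nan
    # frequency-inferable strand: both eafs must be clear of 0.5
    if e.eaf is None or o.eaf is None:
        return "dropped_palindromic", np.nan
    if not (e.eaf < band or e.eaf > 1 - band) or not (o.eaf < band or o.eaf > 1 - band):
        return "dropped_palindromic", np.nan
    same_side = (e.eaf < 0.5) == (o.eaf < 0.5)
    return ("kept", o.beta) if same_side else ("flipped", -o.beta)
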