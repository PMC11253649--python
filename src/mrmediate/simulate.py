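"""Synthetic GWAS summary statistics with known causal structure.

Every pipeline stage in this package is testable without external GWAS
downloads because this module generates the three kinds of input the
screens consume — microbial-abundance exposure panels, blood-metabolite
mediator panels, and case-control disease outcome panels — from an
explicit causal scenario (exposure→mediator, mediator→outcome and direct
exposure→outcome effects, optional per-SNP pleiotropy).

The generative model is the standard two-sample MR summary-statistic
simulation: per-SNP true exposure effects γⱼ are drawn once, the mediator
inherits θ_EM·γⱼ, the outcome inherits θ_direct·γⱼ + θ_MO·(θ_EM·γⱼ) plus
any pleiotropic shortcut αⱼ, and each study observes the truth plus
independent Gaussian estimation noise with

    se = 1 / sqrt(2·maf·(1−maf)·n)

per SNP, where n is the continuous-trait sample size, or the effective
sample size n_eff = 4·n_cases·n_controls/(n_cases+n_controls) on the
log-odds scale for the binary outcome (this effective-n form is exactly a
se-inflation by sqrt(0.25/(φ(1−φ))) relative to a balanced design, and is
how the severe case-control imbalance of a rare-disease GWAS is
emulated).  Reported p-values satisfy the normal Wald relation to the
generated (beta, se) by construction.  Everything is a pure function of
(scenario, seed).

What this generator does NOT emulate: real LD beyond block-constant r²,
population structure, sample overlap between studies, compositionality of
microbial abundances, or non-Gaussian effect-size distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .instruments import ConfounderTable, LdTable
from .io import SnpAssociation, write_summary_stats

__all__ = [
    "CausalScenario",
    "TraitCatalogue",
    "TripletGwas",
    "ScreenWorld",
    "make_microbiota_catalogue",
    "make_metabolite_catalogue",
    "simulate_triplet_gwas",
    "simulate_screen_world",
    "write_fixture_suite",
]

#: printed rank structure of the gut-microbiota exposure catalogue
MICROBIOTA_RANK_COUNTS = {"phylum": 9, "class": 16, "order": 20, "family": 32, "genus": 119}
N_METABOLITES = 1091
N_METABOLITE_RATIOS = 309

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class CausalScenario:
    """Parameters of one simulated exposure→mediator→outcome triplet.

    Defaults mirror the emulated study designs: a microbial-abundance
    exposure GWAS (n ≈ 18,340), a blood-metabolite GWAS (n ≈ 8,299) and a
    rare-disease case-control outcome (91 cases / 174,006 controls, entering
    through the effective sample size).  ``instrument_z`` sets the per-SNP
    association z-score of true instruments (z ≈ 8 comfortably clears
    genome-wide thresholds and F ≥ 10); ``instrument_z_spread`` spreads the
    true strengths uniformly over ``z·(1±spread)`` — spread matters for
    MR-Egger, whose slope is only identified when instrument strengths
    genuinely vary.
    """

    n_snps_exposure: int = 30
    theta_EM: float = 0.5
    theta_MO: float = 0.3
    theta_EO_direct: float = 0.05
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    n_exposure: int = 18_340
    n_mediator: int = 8_299
    n_cases: int = 91
    n_controls: int = 174_006
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    within_block_r2: float = 0.0
    instrument_z: float = 8.0
    instrument_z_spread: float = 0.0
    n_null_snps: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.invalid_fraction < 1):
            raise ValueError("invalid_fraction must lie in [0, 1)")
        for n in (self.n_exposure, self.n_mediator, self.n_cases, self.n_controls):
            if n < 2:
                raise ValueError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @classmethod
    def powered(cls, **overrides) -> "CausalScenario":
        """Large-n preset used for parameter-recovery checks: big cohorts on
        all three sides so estimation noise is small relative to the
        planted effects."""
        base = dict(n_exposure=200_000, n_mediator=200_000, n_cases=20_000,
                    n_controls=180_000, instrument_z=10.0)
        base.update(overrides)
        return cls(**base)

    @property
    def n_outcome_eff(self) -> float:
        return 4.0 * self.n_cases * self.n_controls / (self.n_cases + self.n_controls)

    @property
    def total_effect(self) -> float:
        return self.theta_EO_direct + self.theta_EM * self.theta_MO

    @property
    def mediated_effect(self) -> float:
        return self.theta_EM * self.theta_MO


@dataclass
class TraitCatalogue:
    """Trait inventory of one data source: (trait_id, label, path) rows."""

    kind: str  # microbiota | metabolite | disease
    entries: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def trait_ids(self) -> list[str]:
        return self.entries["trait_id"].tolist()

    def to_tsv(self, path) -> None:
        out = self.entries.copy()
        out["kind"] = self.kind
        out.to_csv(path, sep="\t", index=False)


_SYLLABLES = ["ba", "co", "de", "fi", "ga", "lu", "mi", "no", "pra", "ru",
              "sa", "ter", "vi", "x", "zo", "cu", "lac", "pel", "mon", "thra"]


def _fake_latin(rng: np.random.Generator, n_syll: int = 3) -> str:
    return "".join(rng.choice(_SYLLABLES, size=n_syll)).capitalize()


def make_microbiota_catalogue(seed: int = 0) -> TraitCatalogue:
    """Synthetic 196-taxon catalogue with the emulated rank structure
    (9 phyla, 16 classes, 20 orders, 32 families, 119 genera)."""
    rng = np.random.default_rng(seed)
    rows, seen = [], set()
    for rank, count in MICROBIOTA_RANK_COUNTS.items():
        for _ in range(count):
            name = _fake_latin(rng)
            while name in seen:
                name = _fake_latin(rng)
            seen.add(name)
            rows.append({"trait_id": f"{rank}.{name}", "label": rank, "path": ""})
    return TraitCatalogue("microbiota", pd.DataFrame(rows))


def make_metabolite_catalogue(seed: int = 0, size_factor: float = 1.0) -> TraitCatalogue:
    """Synthetic metabolite catalogue: 1,091 metabolites + 309 ratios at
    full size; ``size_factor`` scales each group by plain rounding."""
    if size_factor <= 0:
        raise ValueError("size_factor must be positive")
    n_met = round(N_METABOLITES * size_factor)
    n_ratio = round(N_METABOLITE_RATIOS * size_factor)
    rows = [{"trait_id": f"met_{i:04d}", "label": "metabolite", "path": ""} for i in range(n_met)]
    rows += [{"trait_id": f"ratio_{i:04d}", "label": "ratio", "path": ""} for i in range(n_ratio)]
    return TraitCatalogue("metabolite", pd.DataFrame(rows))


def _scale_counts(counts: Sequence[int], total: int) -> list[int]:
    """Largest-remainder scaling of a composition to a new total."""
    raw = np.array(counts, float) * total / sum(counts)
    out = np.floor(raw).astype(int)
    rem = raw - out
    for i in np.argsort(-rem)[: total - out.sum()]:
        out[i] += 1
    return out.tolist()


@dataclass
class _Panel:
    """Shared SNP scaffold: ids, positions, alleles, mafs and the LD table."""

    snp: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    eaf: np.ndarray
    maf: np.ndarray
    ld: LdTable


def _make_panel(rng: np.random.Generator, n: int, maf_range, ld_block_size: int,
                within_block_r2: float, start_id: int = 0) -> _Panel:
    snp = np.array([f"rs{start_id + i + 1:07d}" for i in range(n)])
    block = np.arange(n) // ld_block_size
    chrom = (block % 22 + 1).astype(str)
    pos = 1_000_000 + (block // 22) * 30_000_000 + (np.arange(n) % ld_block_size) * 5_000
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])
    maf = rng.uniform(*maf_range, size=n)
    flip = rng.random(n) < 0.5
    eaf = np.where(flip, 1 - maf, maf)
    ld = LdTable()
    for s, c, p in zip(snp, chrom, pos):
        ld.positions[str(s)] = (str(c), int(p))
    if within_block_r2 > 0 and ld_block_size > 1:
        for b in np.unique(block):
            members = snp[block == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld.set_r2(str(members[i]), str(members[j]), within_block_r2)
    return _Panel(snp, chrom, pos, ea, oa, eaf, maf, ld)


def _se_continuous(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _wald_pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * sps.norm.sf(np.abs(beta) / se), _P_FLOOR)


def _records(panel: _Panel, beta: np.ndarray, se: np.ndarray, n: int) -> list[SnpAssociation]:
    pvals = _wald_pvals(beta, se)
    return [
        SnpAssociation(str(s), str(c), int(p), str(a1), str(a2), float(f),
                       float(b), float(e), float(pv), int(n))
        for s, c, p, a1, a2, f, b, e, pv in zip(
            panel.snp, panel.chrom, panel.pos, panel.ea, panel.oa, panel.eaf, beta, se, pvals)
    ]


@dataclass
class TripletGwas:
    """Simulated summary statistics for one exposure/mediator/outcome triplet."""

    exposure: list[SnpAssociation]
    mediator: list[SnpAssociation]
    outcome: list[SnpAssociation]
    ld: LdTable
    truth: dict


def simulate_triplet_gwas(scenario: CausalScenario) -> TripletGwas:
    """Draw one triplet of GWAS summary-statistic sets under the scenario.

    The first ``n_snps_exposure`` panel SNPs are true instruments for the
    exposure; ``n_null_snps`` further SNPs carry no effect anywhere.  An
    ``invalid_fraction`` of the instruments receives a pleiotropic direct
    effect on the outcome drawn from N(pleiotropy_mean, pleiotropy_sd²).
    """
    rng = np.random.default_rng(scenario.seed)
    k = scenario.n_snps_exposure
    n_total = k + scenario.n_null_snps
    panel = _make_panel(rng, n_total, scenario.maf_range,
                        scenario.ld_block_size, scenario.within_block_r2)

    se_exp = _se_continuous(panel.maf, scenario.n_exposure)
    se_med = _se_continuous(panel.maf, scenario.n_mediator)
    se_out = _se_continuous(panel.maf, int(round(scenario.n_outcome_eff)))

    gamma = np.zeros(n_total)
    s = scenario.instrument_z_spread
    z = scenario.instrument_z * rng.uniform(1.0 - s, 1.0 + s, size=k)
    sign = rng.choice([-1.0, 1.0], size=k)
    gamma[:k] = sign * z * se_exp[:k]

    n_invalid = int(round(scenario.invalid_fraction * k))
    invalid_idx = rng.choice(k, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    alpha = np.zeros(n_total)
    if n_invalid:
        alpha[invalid_idx] = rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=n_invalid)

    true_med = scenario.theta_EM * gamma
    true_out = scenario.theta_EO_direct * gamma + scenario.theta_MO * true_med + alpha

    beta_exp = gamma + rng.normal(0.0, se_exp)
    beta_med = true_med + rng.normal(0.0, se_med)
    beta_out = true_out + rng.normal(0.0, se_out)

    n_out_total = scenario.n_cases + scenario.n_controls
    truth = {
        "theta_EM": scenario.theta_EM,
        "theta_MO": scenario.theta_MO,
        "theta_EO_direct": scenario.theta_EO_direct,
        "total_effect": scenario.total_effect,
        "mediated_effect": scenario.mediated_effect,
        "instruments": [str(s) for s in panel.snp[:k]],
        "invalid_instruments": [str(panel.snp[i]) for i in sorted(invalid_idx)],
    }
    return TripletGwas(
        exposure=_records(panel, beta_exp, se_exp, scenario.n_exposure),
        mediator=_records(panel, beta_med, se_med, scenario.n_mediator),
        outcome=_records(panel, beta_out, se_out, n_out_total),
        ld=panel.ld,
        truth=truth,
    )


@dataclass
class ScreenWorld:
    """A miniature three-source study: catalogues, per-trait summary
    statistics over a shared SNP panel, LD, confounder annotations, and the
    planted causal truth."""

    microbiota: TraitCatalogue
    metabolites: TraitCatalogue
    disease_id: str
    stats: dict[str, list[SnpAssociation]]
    ld: LdTable
    confounders: ConfounderTable
    truth: dict

    @property
    def microbiota_stats(self) -> dict[str, list[SnpAssociation]]:
        return {t: self.stats[t] for t in self.microbiota.trait_ids}

    @property
    def metabolite_stats(self) -> dict[str, list[SnpAssociation]]:
        return {t: self.stats[t] for t in self.metabolites.trait_ids}


def simulate_screen_world(
    seed: int = 0,
    n_microbiota: int = 20,
    n_metabolites: int = 30,
    snps_per_microbiota: int = 140,
    snps_per_metabolite: int = 24,
    snps_disease: int = 8,
    n_null_snps: int = 40,
    theta_EM: float = 0.5,
    theta_MO: float = 0.3,
    theta_EO_direct: float = 0.05,
    theta_direct_only: float = 0.25,
    theta_feedback: float = 0.0,
    n_microbiota_gwas: int = 640_000,
    n_metabolite_gwas: int = 40_000,
    n_cases: int = 50_000,
    n_controls: int = 150_000,
    microbiota_z: float = 16.0,
    metabolite_z: float = 24.0,
    disease_z: float = 20.0,
    instrument_z_spread: float = 0.5,
    ld_block_size: int = 2,
    within_block_r2: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> ScreenWorld:
    """Build a three-screen world with planted causal structure.

    Planted truth: microbiota #0 and #1 act on the outcome through
    metabolite #0 (θ_EM → θ_MO) plus a small direct effect θ_EO_direct;
    microbiota #2 acts on the outcome directly (θ_direct_only) with no
    metabolite link; metabolite #1 is causal for the outcome on its own
    (−θ_MO, protective); all other traits are null.  With
    ``theta_feedback`` ≠ 0 the disease feeds back onto microbiota #0
    (bidirectional pair).  Every trait's statistics cover the full shared
    panel, so each screen sees the same SNP universe.

    Per-source instrument strength is deliberately asymmetric, mirroring
    the emulated designs: many moderate instruments (z ≈ 8) for microbial
    abundance, few strong ones (z ≈ 20) for metabolites and the disease.
    The moderate microbiota z also keeps the microbe loci below the
    genome-wide threshold in the mediator's own GWAS (borrowed-instrument
    z ≈ θ_EM·z·sqrt(n_metab/n_micro) ≈ 4), so the metabolite→disease
    screen is instrumented almost purely by the metabolite's own loci —
    the exposure-side exchange rate between instrument precision and
    cross-contamination is fixed at θ_EM, and this is the balanced point.
    """
    rng = np.random.default_rng(seed)
    micro_cat = _world_microbiota_catalogue(rng, n_microbiota)
    metab_cat = make_metabolite_catalogue(seed=seed)
    metab_ids = metab_cat.trait_ids[:n_metabolites]
    metab_cat = TraitCatalogue("metabolite", metab_cat.entries.iloc[:n_metabolites].reset_index(drop=True))
    micro_ids = micro_cat.trait_ids
    disease_id = "disease.GBM_syn"

    n_panel = (n_microbiota * snps_per_microbiota + n_metabolites * snps_per_metabolite
               + snps_disease + n_null_snps)
    panel = _make_panel(rng, n_panel, maf_range, ld_block_size, within_block_r2)

    # instrument slices per trait
    slices: dict[str, slice] = {}
    cursor = 0
    for t in micro_ids:
        slices[t] = slice(cursor, cursor + snps_per_microbiota)
        cursor += snps_per_microbiota
    for t in metab_ids:
        slices[t] = slice(cursor, cursor + snps_per_metabolite)
        cursor += snps_per_metabolite
    slices[disease_id] = slice(cursor, cursor + snps_disease)

    se_micro = _se_continuous(panel.maf, n_microbiota_gwas)
    se_metab = _se_continuous(panel.maf, n_metabolite_gwas)
    n_eff = int(round(4.0 * n_cases * n_controls / (n_cases + n_controls)))
    se_out = _se_continuous(panel.maf, n_eff)
    se_for = {t: se_micro for t in micro_ids}
    se_for.update({t: se_metab for t in metab_ids})
    se_for[disease_id] = se_out
    n_for = {t: n_microbiota_gwas for t in micro_ids}
    n_for.update({t: n_metabolite_gwas for t in metab_ids})
    n_for[disease_id] = n_cases + n_controls

    z_for = {t: microbiota_z for t in micro_ids}
    z_for.update({t: metabolite_z for t in metab_ids})
    z_for[disease_id] = disease_z

    def _gamma(trait: str) -> np.ndarray:
        g = np.zeros(n_panel)
        sl = slices[trait]
        size = sl.stop - sl.start
        z = z_for[trait] * rng.uniform(1.0 - instrument_z_spread, 1.0 + instrument_z_spread, size=size)
        g[sl] = rng.choice([-1.0, 1.0], size=size) * z * se_for[trait][sl]
        return g

    gammas = {t: _gamma(t) for t in list(micro_ids) + list(metab_ids) + [disease_id]}

    mediated_microbes = micro_ids[:2]
    direct_microbe = micro_ids[2]
    mediator = metab_ids[0]
    solo_metabolite = metab_ids[1]

    true_beta: dict[str, np.ndarray] = {}
    for t in micro_ids:
        true_beta[t] = gammas[t].copy()
    if theta_feedback:
        true_beta[mediated_microbes[0]] = true_beta[mediated_microbes[0]] + theta_feedback * gammas[disease_id]
    for t in metab_ids:
        true_beta[t] = gammas[t].copy()
    for m in mediated_microbes:
        true_beta[mediator] = true_beta[mediator] + theta_EM * gammas[m]

    out = gammas[disease_id].copy()
    out += theta_MO * true_beta[mediator]          # carries θ_MO·θ_EM·γ_M for mediated microbes
    out -= theta_MO * gammas[solo_metabolite]      # protective solo metabolite
    for m in mediated_microbes:
        out += theta_EO_direct * gammas[m]
    out += theta_direct_only * gammas[direct_microbe]
    true_beta[disease_id] = out

    stats: dict[str, list[SnpAssociation]] = {}
    for t in list(micro_ids) + list(metab_ids) + [disease_id]:
        beta_hat = true_beta[t] + rng.normal(0.0, se_for[t])
        stats[t] = _records(panel, beta_hat, se_for[t], n_for[t])

    # confounder annotations on two instruments of a null microbe
    conf_target = micro_ids[5] if n_microbiota > 5 else micro_ids[-1]
    conf_snps = panel.snp[slices[conf_target]][:2]
    confounders = ConfounderTable(pd.DataFrame(
        {"snp": [str(s) for s in conf_snps],
         "trait": ["synthetic_confounder"] * len(conf_snps),
         "pval": [1e-20] * len(conf_snps)}))

    truth = {
        "disease_id": disease_id,
        "mediated_triplets": [
            {"exposure": m, "mediator": mediator, "outcome": disease_id,
             "theta_EM": theta_EM, "theta_MO": theta_MO,
             "theta_EO_direct": theta_EO_direct,
             "total_effect": theta_EO_direct + theta_EM * theta_MO,
             "mediated_effect": theta_EM * theta_MO}
            for m in mediated_microbes
        ],
        "direct_only_microbiota": [{"exposure": direct_microbe, "effect": theta_direct_only}],
        "causal_metabolites": {mediator: theta_MO, solo_metabolite: -theta_MO},
        "feedback": {"exposure": mediated_microbes[0], "theta": theta_feedback} if theta_feedback else None,
        "confounded_trait": conf_target,
        "seed": seed,
    }
    return ScreenWorld(micro_cat, metab_cat, disease_id, stats, panel.ld, confounders, truth)


def _world_microbiota_catalogue(rng: np.random.Generator, n: int) -> TraitCatalogue:
    ranks = list(MICROBIOTA_RANK_COUNTS)
    counts = _scale_counts(list(MICROBIOTA_RANK_COUNTS.values()), n)
    rows, seen = [], set()
    for rank, count in zip(ranks, counts):
        for _ in range(count):
            name = _fake_latin(rng)
            while name in seen:
                name = _fake_latin(rng)
            seen.add(name)
            rows.append({"trait_id": f"{rank}.{name}", "label": rank, "path": ""})
    return TraitCatalogue("microbiota", pd.DataFrame(rows))


def write_fixture_suite(out_dir: str | Path, seed: int = 0, **world_kwargs) -> dict:
    """Write a miniature three-screen world to disk and return its manifest.

    Emits one canonical summary-statistics TSV per trait, the LD and
    confounder tables, both catalogues, and ``manifest.json`` recording
    every file together with the planted truth.  Identical seeds produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = simulate_screen_world(seed=seed, **world_kwargs)

    files: dict[str, str] = {}

    def _write_trait(trait_id: str) -> str:
        fname = f"{trait_id.replace('/', '_').replace('.', '_')}.tsv"
        write_summary_stats(world.stats[trait_id], out / fname)
        files[trait_id] = fname
        return fname

    for cat in (world.microbiota, world.metabolites):
        paths = [_write_trait(t) for t in cat.trait_ids]
        cat.entries = cat.entries.assign(path=paths)
    _write_trait(world.disease_id)

    world.ld.to_tsv(out / "ld.tsv")
    world.confounders.rows.to_csv(out / "confounders.tsv", sep="\t", index=False)
    world.microbiota.to_tsv(out / "microbiota_catalogue.tsv")
    world.metabolites.to_tsv(out / "metabolite_catalogue.tsv")

    manifest = {
        "seed": seed,
        "files": files,
        "ld": "ld.tsv",
        "confounders": "confounders.tsv",
        "catalogues": {"microbiota": "microbiota_catalogue.tsv", "metabolite": "metabolite_catalogue.tsv"},
        "truth": world.truth,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
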