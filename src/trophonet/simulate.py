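"""Synthetic eutrophication-gradient data generator.

Emulates the statistical structure the pipeline assumes, so every stage is
testable without field data, and emits the planted truth alongside the
data so recovery can be scored exactly:

* per-site water chemistry back-solved from a target composite TSI drawn
  in each trophic group's range (L: [30, 50], M: (50, 60], H: (60, 70]),
  then jittered with multiplicative lognormal noise;
* a phytoplankton community whose phylum mix shifts from diatom
  (Bacillariophyta) dominance at low TSI to cyanobacteria (Cyanophyta)
  dominance at high TSI along a logistic turnover;
* a bacterial community dominated by Proteobacteria (~60% of reads) whose
  within-phylum evenness — hence Shannon diversity — declines as trophic
  state rises;
* planted signed correlation blocks within and across kingdoms, realized
  through a Gaussian copula over negative-binomial marginals so that rank
  correlations (what Spearman sees) are controlled while counts stay
  overdispersed.

The correlation structure is a one-factor-per-block model: members of a
block load ±sqrt(r_within) on the block's latent factor.  Module fusion
along the gradient is hierarchical: at L every factor is independent; at M
the within-kingdom boundaries collapse (the bacterial factors share one
parent, the phytoplankton and mixed factors another); at H one global
parent couples every block.  Coupled factors correlate at
``coupling_strength``, so modularity falls L→H; in the mixed
phytoplankton–bacteria block an increasing number of phytoplankton members
flip to negative loadings, so the negative-edge share rises L→H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, expit

from .community import AbundanceTable
from .trophic import (
    TSI_COEFFICIENTS,
    WaterChemistryRecord,
    classify_trophic_state,
)

__all__ = [
    "GradientScenario",
    "SyntheticTruth",
    "SimulatedDataset",
    "generate_chemistry",
    "generate_communities",
    "generate_dataset",
    "score_recovery",
]

GROUPS = ("L", "M", "H")

# Phytoplankton phyla with taxon counts (30 taxa total); the minor phyla get
# fixed raw weights, diatoms and cyanobacteria trade dominance with TSI.
PHYTO_PHYLA = {
    "Bacillariophyta": 8,
    "Cyanophyta": 7,
    "Chlorophyta": 6,
    "Pyrrophyta": 6,
    "Cryptophyta": 2,
    "Euglenophyta": 1,
}
PHYTO_MINOR_WEIGHTS = {
    "Chlorophyta": 0.25,
    "Pyrrophyta": 0.08,
    "Cryptophyta": 0.07,
    "Euglenophyta": 0.05,
}

# Bacterial phyla with taxon counts (70 taxa) and base phylum weights.
BACT_PHYLA = {
    "Proteobacteria": 28,
    "Bacteroidota": 10,
    "Actinobacteriota": 10,
    "Cyanobacteria": 8,
    "Firmicutes": 6,
    "Verrucomicrobiota": 4,
    "Planctomycetota": 4,
}
BACT_PHYLUM_WEIGHTS = {
    "Proteobacteria": 0.60,
    "Bacteroidota": 0.12,
    "Actinobacteriota": 0.10,
    "Cyanobacteria": 0.06,
    "Firmicutes": 0.05,
    "Verrucomicrobiota": 0.04,
    "Planctomycetota": 0.03,
}

# Correlation blocks: (kingdom prefix, member indices within that kingdom).
# Blocks sit in mid-abundance phyla (Bacteroidota, Actinobacteriota,
# Chlorophyta, Pyrrophyta) rather than the dominant ones, so that the
# compositional closure of the relative-abundance transform does not turn a
# block's coherent swings into strong unplanted correlations elsewhere.
# The mixed block spans five bacterial Cyanobacteria and five Cyanophyta
# (the taxa whose coupling inverts as eutrophication rises).
# Index map — phyto: Bacillariophyta 0-7, Cyanophyta 8-14, Chlorophyta
# 15-20, Pyrrophyta 21-26, Cryptophyta 27-28, Euglenophyta 29; bacteria:
# Proteobacteria 0-27, Bacteroidota 28-37, Actinobacteriota 38-47,
# Cyanobacteria 48-55, Firmicutes 56-61, Verrucomicrobiota 62-65,
# Planctomycetota 66-69.
BLOCK_LAYOUT = {
    "bactA": [("B", i) for i in range(28, 36)],    # Bacteroidota
    "bactB": [("B", i) for i in range(38, 46)],    # Actinobacteriota
    "phytoA": [("P", i) for i in range(15, 21)],   # Chlorophyta
    "phytoB": [("P", i) for i in range(21, 27)],   # Pyrrophyta
    "mixed": [("B", i) for i in range(48, 53)] + [("P", i) for i in range(8, 13)],
}

# Hierarchical factor-parent structure driving module fusion: at M the
# within-kingdom module boundaries collapse (bacterial factors share one
# parent, phytoplankton + mixed factors another); at H a single parent
# couples every block.  Coupled factors correlate at coupling_strength.
DEFAULT_PARENT_GROUPS = {
    "L": [["bactA"], ["bactB"], ["phytoA"], ["phytoB"], ["mixed"]],
    "M": [["bactA", "bactB"], ["phytoA", "phytoB", "mixed"]],
    "H": [["bactA", "bactB", "phytoA", "phytoB", "mixed"]],
}


def _group_mid(lo: float, hi: float) -> float:
    return 0.5 * (lo + hi)


@dataclass
class GradientScenario:
    """Configuration of one synthetic gradient study.

    Defaults are the conditions the pipeline is exercised under: 30 sites
    per trophic group, group TSI ranges matching the classification bands,
    5% lognormal chemistry noise, 30 phytoplankton and 70 bacterial taxa,
    library size above the 27,000-read rarefaction depth.  The correlation
    block parameters are free parameters chosen for clear recoverability,
    not estimates of any field system.
    """

    n_sites_per_group: dict = field(
        default_factory=lambda: {"L": 30, "M": 30, "H": 30}
    )
    target_tsi_ranges: dict = field(
        default_factory=lambda: {"L": (30.0, 50.0), "M": (50.0, 60.0), "H": (60.0, 70.0)}
    )
    chemistry_noise_sd: float = 0.05
    n_phyto_taxa: int = 30
    n_bact_taxa: int = 70
    diatom_to_cyano_slope: float = 0.25     # logistic slope per TSI unit
    turnover_midpoint_tsi: float = 55.0
    proteobacteria_base_fraction: float = 0.60
    shannon_decline_rate: float = 0.02      # evenness tilt per TSI unit
    within_block_r: float = 0.9             # latent correlation inside a block
    coupling_strength: float = 0.8          # factor correlation under one parent
    factor_parent_groups: dict = field(
        default_factory=lambda: {g: [list(p) for p in DEFAULT_PARENT_GROUPS[g]]
                                 for g in DEFAULT_PARENT_GROUPS}
    )
    mixed_negative_members: dict = field(
        default_factory=lambda: {"L": 0, "M": 3, "H": 5}
    )
    nb_dispersion: float = 5.0              # negative-binomial size parameter
    library_size: int = 33000               # reads per bacterial sample
    phyto_total: int = 50000                # expected cells per phyto sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phyto_taxa != sum(PHYTO_PHYLA.values()):
            raise ValueError(f"n_phyto_taxa must be {sum(PHYTO_PHYLA.values())}")
        if self.n_bact_taxa != sum(BACT_PHYLA.values()):
            raise ValueError(f"n_bact_taxa must be {sum(BACT_PHYLA.values())}")
        if not 0 < self.proteobacteria_base_fraction < 1:
            raise ValueError("proteobacteria_base_fraction must lie in (0, 1)")
        if not 0 < self.within_block_r < 1:
            raise ValueError("within_block_r must lie in (0, 1)")
        if not 0 <= self.coupling_strength < 1:
            raise ValueError("coupling_strength must lie in [0, 1)")
        for g, parents in self.factor_parent_groups.items():
            named = [b for p in parents for b in p]
            if sorted(named) != sorted(BLOCK_LAYOUT):
                raise ValueError(
                    f"factor_parent_groups[{g}] must partition {sorted(BLOCK_LAYOUT)}"
                )
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for g, (lo, hi) in self.target_tsi_ranges.items():
            if not lo < hi:
                raise ValueError(f"empty TSI range for group {g}")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_tsi_ranges"] = {g: list(v) for g, v in d["target_tsi_ranges"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GradientScenario":
        d = dict(d)
        if "target_tsi_ranges" in d:
            d["target_tsi_ranges"] = {
                g: tuple(v) for g, v in d["target_tsi_ranges"].items()
            }
        return cls(**d)

    # ---- derived helpers ----------------------------------------------
    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed substream of the scenario seed; adding a stage never
        perturbs earlier stages' draws."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )

    def taxon_ids(self) -> tuple[list[str], list[str]]:
        phyto = [f"P{i + 1:03d}" for i in range(self.n_phyto_taxa)]
        bact = [f"B{i + 1:03d}" for i in range(self.n_bact_taxa)]
        return phyto, bact


@dataclass
class SyntheticTruth:
    """Everything needed to score pipeline recovery exactly."""

    sites: pd.DataFrame              # site_id, group, target_tsi, true_label
    latent_correlation: dict         # group -> taxa x taxa DataFrame
    block_membership: dict           # taxon_id -> block name (absent = background)
    dominance: dict                  # group -> planted composition fractions
    scenario: GradientScenario


@dataclass
class SimulatedDataset:
    chemistry: list
    phyto: AbundanceTable
    bact: AbundanceTable
    taxonomy: pd.DataFrame
    truth: SyntheticTruth


def invert_tsi_component(kind: str, tsi: float) -> float:
    """Measurement whose component score equals ``tsi``: exp((tsi/10 − a)/b)."""
    a, b = TSI_COEFFICIENTS[kind]
    return math.exp((tsi / 10.0 - a) / b)


def generate_chemistry(
    scenario: GradientScenario, seed: int | None = None
) -> tuple[list[WaterChemistryRecord], SyntheticTruth]:
    """Draw per-site target TSIs and back-solve noisy chemistry.

    Each site's four components are solved at the same composite target
    (the weights sum to 1, so the zero-noise composite equals the target
    exactly), then jittered multiplicatively by exp(N(0, noise_sd)).
    """
    rng = scenario.rng(0) if seed is None else np.random.default_rng(seed)
    records: list[WaterChemistryRecord] = []
    rows = []
    for group in GROUPS:
        n = scenario.n_sites_per_group.get(group, 0)
        lo, hi = scenario.target_tsi_ranges[group]
        targets = rng.uniform(lo, hi, size=n)
        for i, target in enumerate(targets):
            site = f"{group}{i + 1:02d}"
            vals = {}
            for kind in ("chl_a", "tn", "tp", "sd"):
                base = invert_tsi_component(kind, target)
                vals[kind] = base * math.exp(
                    scenario.chemistry_noise_sd * rng.standard_normal()
                )
            records.append(
                WaterChemistryRecord(
                    site_id=site, tn=vals["tn"], tp=vals["tp"],
                    chl_a=vals["chl_a"], secchi=vals["sd"],
                )
            )
            rows.append({
                "site_id": site, "group": group,
                "target_tsi": float(target),
                "true_label": classify_trophic_state(float(target)),
            })
    sites = pd.DataFrame(rows).set_index("site_id")
    truth = SyntheticTruth(
        sites=sites, latent_correlation={}, block_membership={},
        dominance={}, scenario=scenario,
    )
    return records, truth


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

def _taxonomy_frame(scenario: GradientScenario) -> pd.DataFrame:
    phyto_ids, bact_ids = scenario.taxon_ids()
    rows = []
    i = 0
    for phylum, k in PHYTO_PHYLA.items():
        for _ in range(k):
            rows.append({"taxon_id": phyto_ids[i], "kingdom": "phytoplankton",
                         "phylum": phylum, "genus": ""})
            i += 1
    i = 0
    for phylum, k in BACT_PHYLA.items():
        for _ in range(k):
            rows.append({"taxon_id": bact_ids[i], "kingdom": "bacteria",
                         "phylum": phylum, "genus": ""})
            i += 1
    return pd.DataFrame(rows).set_index("taxon_id")


def _block_loadings(scenario: GradientScenario, group: str, taxa: list[str]):
    """Loading matrix Λ (taxa × blocks) and factor correlation Ψ for a group."""
    phyto_ids, bact_ids = scenario.taxon_ids()
    lam = math.sqrt(scenario.within_block_r)
    block_names = list(BLOCK_LAYOUT)
    L = np.zeros((len(taxa), len(block_names)))
    index = {t: i for i, t in enumerate(taxa)}
    n_neg = scenario.mixed_negative_members.get(group, 0)
    membership: dict[str, str] = {}
    for b, name in enumerate(block_names):
        neg_assigned = 0
        for prefix, k in BLOCK_LAYOUT[name]:
            tid = (bact_ids if prefix == "B" else phyto_ids)[k]
            sign = 1.0
            if name == "mixed" and prefix == "P" and neg_assigned < n_neg:
                sign = -1.0
                neg_assigned += 1
            L[index[tid], b] = sign * lam
            membership[tid] = name
    # factor correlation: coupling_strength between factors sharing a parent
    psi = np.eye(len(block_names))
    parent_of = {
        b: pi
        for pi, parent in enumerate(scenario.factor_parent_groups[group])
        for b in parent
    }
    for i, bi in enumerate(block_names):
        for j, bj in enumerate(block_names):
            if i != j and parent_of[bi] == parent_of[bj]:
                psi[i, j] = scenario.coupling_strength
    return L, psi, membership


def _phyto_phylum_weights(scenario: GradientScenario, tsi: float) -> dict:
    s = scenario.diatom_to_cyano_slope
    mid = scenario.turnover_midpoint_tsi
    raw = dict(PHYTO_MINOR_WEIGHTS)
    raw["Bacillariophyta"] = float(expit(-s * (tsi - mid)))
    raw["Cyanophyta"] = float(expit(s * (tsi - mid)))
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _bact_phylum_weights(scenario: GradientScenario) -> dict:
    w = dict(BACT_PHYLUM_WEIGHTS)
    # rescale so Proteobacteria sits at the configured base fraction
    other = sum(v for k, v in w.items() if k != "Proteobacteria")
    target_other = 1.0 - scenario.proteobacteria_base_fraction
    out = {
        k: (scenario.proteobacteria_base_fraction if k == "Proteobacteria"
            else v * target_other / other)
        for k, v in w.items()
    }
    return out


def _tilt(p: np.ndarray, beta: float) -> np.ndarray:
    q = np.power(p, beta)
    return q / q.sum()


def _composition(
    scenario: GradientScenario,
    taxonomy: pd.DataFrame,
    base_props: dict,
    group_tsi: float,
    kingdom: str,
) -> pd.Series:
    """Per-taxon expected relative abundance for one group."""
    beta = 1.0 + scenario.shannon_decline_rate * (group_tsi - 45.0)
    beta = max(beta, 0.1)
    if kingdom == "phytoplankton":
        phylum_w = _phyto_phylum_weights(scenario, group_tsi)
    else:
        phylum_w = _bact_phylum_weights(scenario)
    taxa = taxonomy.index[taxonomy["kingdom"] == kingdom]
    frac = pd.Series(0.0, index=taxa)
    for phylum, w in phylum_w.items():
        members = taxa[taxonomy.loc[taxa, "phylum"] == phylum]
        props = _tilt(np.asarray(base_props[kingdom][phylum]), beta)
        frac.loc[members] = w * props
    return frac / frac.sum()


def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative values to integers summing exactly to ``total``,
    preserving the within-vector ordering."""
    if values.sum() <= 0:
        raise ValueError("cannot rescale an all-zero sample")
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(np.int64)
    shortfall = total - int(floors.sum())
    if shortfall > 0:
        order = np.argsort(-(scaled - floors), kind="mergesort")
        floors[order[:shortfall]] += 1
    return floors


def generate_communities(
    scenario: GradientScenario,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> tuple[AbundanceTable, AbundanceTable, pd.DataFrame]:
    """Draw phytoplankton and bacterial count tables for the chemistry sites.

    Per group, taxa share a Gaussian copula with the planted block
    correlation matrix; marginals are negative binomial with means set by
    the group's composition.  Bacterial columns are rescaled to exactly
    ``library_size`` reads (largest-remainder rounding, rank-preserving
    within a sample); phytoplankton counts are left as drawn (cells/L
    scale).  ``truth`` is updated in place with the latent correlation
    matrices, block membership and planted dominance fractions.
    """
    rng = scenario.rng(1) if seed is None else np.random.default_rng(seed)
    taxonomy = _taxonomy_frame(scenario)
    phyto_ids, bact_ids = scenario.taxon_ids()
    all_taxa = phyto_ids + bact_ids

    # within-phylum base proportions, drawn once per scenario
    base_rng = scenario.rng(2)
    base_props = {"phytoplankton": {}, "bacteria": {}}
    for phylum, k in PHYTO_PHYLA.items():
        base_props["phytoplankton"][phylum] = base_rng.dirichlet(np.full(k, 2.0))
    for phylum, k in BACT_PHYLA.items():
        base_props["bacteria"][phylum] = base_rng.dirichlet(np.full(k, 2.0))

    k_disp = scenario.nb_dispersion
    phyto_cols: dict[str, np.ndarray] = {}
    bact_cols: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}

    for group in GROUPS:
        sites = truth.sites.index[truth.sites["group"] == group]
        if len(sites) == 0:
            continue
        lo, hi = scenario.target_tsi_ranges[group]
        group_tsi = _group_mid(lo, hi)
        L, psi, membership = _block_loadings(scenario, group, all_taxa)
        R = L @ psi @ L.T
        np.fill_diagonal(R, 1.0)
        truth.latent_correlation[group] = pd.DataFrame(
            R, index=all_taxa, columns=all_taxa
        )
        truth.block_membership = membership  # identical layout across groups

        frac_p = _composition(scenario, taxonomy, base_props, group_tsi, "phytoplankton")
        frac_b = _composition(scenario, taxonomy, base_props, group_tsi, "bacteria")
        mu = np.concatenate([
            frac_p.loc[phyto_ids].to_numpy() * scenario.phyto_total,
            frac_b.loc[bact_ids].to_numpy() * scenario.library_size,
        ])
        truth.dominance[group] = {
            "diatom_fraction": float(
                frac_p[taxonomy.loc[phyto_ids, "phylum"] == "Bacillariophyta"].sum()
            ),
            "cyanophyta_fraction": float(
                frac_p[taxonomy.loc[phyto_ids, "phylum"] == "Cyanophyta"].sum()
            ),
            "proteobacteria_fraction": float(
                frac_b[taxonomy.loc[bact_ids, "phylum"] == "Proteobacteria"].sum()
            ),
        }
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
        p_nb = k_disp / (k_disp + mu)
        for site in sites:
            z = chol @ rng.standard_normal(len(all_taxa))
            u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
            counts = sps.nbinom.ppf(u, k_disp, p_nb).astype(np.int64)
            n_p = len(phyto_ids)
            phyto_cols[site] = counts[:n_p]
            bact_cols[site] = _largest_remainder(
                counts[n_p:].astype(float), scenario.library_size
            )
            group_of[site] = group

    group_series = pd.Series(group_of, name="group")
    phyto = AbundanceTable(
        counts=pd.DataFrame(phyto_cols, index=phyto_ids),
        taxonomy=taxonomy,
        group=group_series,
        meta={"kingdom": "phytoplankton", "units": "cells"},
    )
    bact = AbundanceTable(
        counts=pd.DataFrame(bact_cols, index=bact_ids),
        taxonomy=taxonomy,
        group=group_series,
        meta={"kingdom": "bacteria", "units": "reads",
              "library_size": scenario.library_size},
    )
    return phyto, bact, taxonomy


def generate_dataset(scenario: GradientScenario) -> SimulatedDataset:
    """Full synthetic study: chemistry, both communities, taxonomy, truth."""
    chemistry, truth = generate_chemistry(scenario)
    phyto, bact, taxonomy = generate_communities(scenario, truth)
    return SimulatedDataset(
        chemistry=chemistry, phyto=phyto, bact=bact,
        taxonomy=taxonomy, truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def _edge_metrics(
    network, latent: pd.DataFrame, strong: float, null: float
) -> dict:
    """Recall/sign accuracy over strongly planted pairs and spurious rate
    over null pairs; pairs of intermediate planted correlation (factor
    coupling products) are excluded from both."""
    edges = {frozenset((u, v)): d["rho"] for u, v, d in network.graph.edges(data=True)}
    taxa = list(latent.index)
    R = latent.to_numpy()
    strong_pairs = []
    null_pairs = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = R[i, j]
            pair = frozenset((taxa[i], taxa[j]))
            if abs(r) >= strong:
                strong_pairs.append((pair, r))
            elif abs(r) < null:
                null_pairs.append(pair)
    n_strong = len(strong_pairs)
    recovered = [(p, r) for p, r in strong_pairs if p in edges]
    sign_ok = sum(1 for p, r in recovered if math.copysign(1, edges[p]) == math.copysign(1, r))
    spurious = sum(1 for p in null_pairs if p in edges)
    return {
        "n_strong_pairs": n_strong,
        "recall": len(recovered) / n_strong if n_strong else math.nan,
        "sign_accuracy": sign_ok / len(recovered) if recovered else math.nan,
        "n_null_pairs": len(null_pairs),
        "spurious_rate": spurious / len(null_pairs) if null_pairs else math.nan,
    }


def score_recovery(
    truth: SyntheticTruth,
    assessments=None,
    networks: dict | None = None,
    topologies: list | None = None,
    shannon_by_group: dict | None = None,
    strong_threshold: float = 0.8,
    null_threshold: float = 0.3,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Reports trophic class accuracy, per-group planted-edge recall /
    spurious-edge rate / sign accuracy, and L→M→H direction agreement for
    Shannon diversity (declining), modularity (declining) and negative-edge
    percentage (rising).
    """
    report: dict = {}
    if assessments is not None:
        ids = {a.site_id for a in assessments}
        missing = set(truth.sites.index) - ids
        if missing:
            raise ValueError(f"assessments missing sites: {sorted(missing)[:5]}")
        correct = sum(
            1 for a in assessments
            if a.site_id in truth.sites.index
            and a.label == truth.sites.loc[a.site_id, "true_label"]
        )
        report["class_accuracy"] = correct / len(truth.sites)
    if networks is not None:
        per_group = {}
        for group, net in networks.items():
            latent = truth.latent_correlation[group]
            per_group[group] = _edge_metrics(
                net, latent, strong_threshold, null_threshold
            )
        report["edges"] = per_group
    if topologies is not None:
        by_group = {t.group: t for t in topologies}
        ordered = [by_group[g] for g in GROUPS if g in by_group]
        mods = [t.modularity for t in ordered]
        negs = [t.pct_negative_edges for t in ordered]
        report["modularity_values"] = mods
        report["pct_negative_values"] = negs
        report["modularity_decreasing"] = bool(np.all(np.diff(mods) < 0))
        report["pct_negative_increasing"] = bool(np.all(np.diff(negs) > 0))
    if shannon_by_group is not None:
        vals = [shannon_by_group[g] for g in GROUPS if g in shannon_by_group]
        report["shannon_values"] = list(map(float, vals))
        report["shannon_decreasing"] = bool(np.all(np.diff(vals) < 0))
    return report
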