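"""Synthetic reference worlds, cohorts, placements and FASTQ runs.

This module generates data with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised without any
external download:

* a curated-style reference world (aligned 16S-like sequences, a taxonomy
  with provisional taxa, a reference tree with monophyletic species clades);
* cohorts of vaginal communities: Lactobacillus-dominated non-BV samples
  versus diverse BV samples with co-occurring sub-groups of BV-associated
  anaerobes, race x BV prevalence interactions, Nugent scores and the four
  Amsel signs driven by taxon abundances;
* phylogenetic placements whose posterior mass concentrates on the source
  species' clade; and
* barcoded FASTQ runs with deliberately injected QC failures.

Sequence evolution is i.i.d. per-site substitution on a fixed clade
skeleton: only pairwise distances matter downstream, so no attempt is made
to model rate heterogeneity, indels or chimeras. All randomness flows
through one ``numpy.random.Generator`` per call; fixed seeds reproduce
bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import Attachment, CountMatrix, PlacedRead, validate_sample_meta
from .errors import DataError, ParameterError
from .taxonomy import Taxonomy
from .tree import PhyloTree

_BASES = np.array(list("ACGT"))

#: (species, genus, family, order, provisional) — taxa of the vaginal niche.
VAGINAL_TAXA: List[Tuple[str, str, str, str, bool]] = [
    ("Lactobacillus_crispatus", "Lactobacillus", "Lactobacillaceae", "Lactobacillales", False),
    ("Lactobacillus_iners", "Lactobacillus", "Lactobacillaceae", "Lactobacillales", False),
    ("Gardnerella_vaginalis", "Gardnerella", "Bifidobacteriaceae", "Bifidobacteriales", False),
    ("Atopobium_vaginae", "Atopobium", "Coriobacteriaceae", "Coriobacteriales", False),
    ("BVAB1", "BVAB", "Lachnospiraceae", "Clostridiales", True),
    ("BVAB2", "BVAB", "Lachnospiraceae", "Clostridiales", True),
    ("Megasphaera_sp_type_1", "Megasphaera", "Veillonellaceae", "Clostridiales", True),
    ("Leptotrichia_amnionii", "Leptotrichia", "Leptotrichiaceae", "Fusobacteriales", False),
    ("Sneathia_sanguinegens", "Sneathia", "Leptotrichiaceae", "Fusobacteriales", False),
    ("Eggerthella_sp", "Eggerthella", "Coriobacteriaceae", "Coriobacteriales", True),
    ("Prevotella_amnii", "Prevotella", "Prevotellaceae", "Bacteroidales", False),
    ("Prevotella_timonensis", "Prevotella", "Prevotellaceae", "Bacteroidales", False),
    ("Lactobacillus_jensenii", "Lactobacillus", "Lactobacillaceae", "Lactobacillales", False),
    ("Lactobacillus_gasseri", "Lactobacillus", "Lactobacillaceae", "Lactobacillales", False),
    ("Dialister_micraerophilus", "Dialister", "Veillonellaceae", "Clostridiales", False),
    ("Dialister_sp_type_2", "Dialister", "Veillonellaceae", "Clostridiales", True),
    ("BVAB3", "BVAB", "Lachnospiraceae", "Clostridiales", True),
    ("Prevotella_genogroup_3", "Prevotella", "Prevotellaceae", "Bacteroidales", True),
    ("Parvimonas_micra", "Parvimonas", "Peptoniphilaceae", "Clostridiales", False),
    ("Aerococcus_christensenii", "Aerococcus", "Aerococcaceae", "Lactobacillales", False),
]


@dataclass
class ReferenceWorld:
    """Aligned reference sequences + taxonomy + tree, with leaf labels."""

    sequences: Dict[str, str]           # sequence id -> aligned sequence
    taxonomy: Taxonomy
    tree: PhyloTree
    leaf_taxids: Dict[str, str]         # leaf/sequence id -> species taxid
    species: List[str]                  # species taxids in simulation order

    def species_names(self) -> List[str]:
        return [self.taxonomy.name(t) for t in self.species]

    def clade_leaves(self, taxid: str) -> List[str]:
        return sorted(l for l, t in self.leaf_taxids.items() if t == taxid)


def _taxon_catalog(n_taxa: int) -> List[Tuple[str, str, str, str, bool]]:
    cat = list(VAGINAL_TAXA)
    i = 1
    while len(cat) < n_taxa:
        cat.append(
            (f"Clostridiales_genomosp_{i}", "Clostridiales_genomosp",
             "Lachnospiraceae", "Clostridiales", True)
        )
        i += 1
    return cat[:n_taxa]


def _build_taxonomy(catalog: Sequence[Tuple[str, str, str, str, bool]]) -> Taxonomy:
    tax = Taxonomy()
    tax.add("r__Root", "Root", "root", None)
    for species, genus, family, order, provisional in catalog:
        o, f, g, s = f"o__{order}", f"f__{family}", f"g__{genus}", f"s__{species}"
        if o not in tax:
            tax.add(o, order, "order", "r__Root")
        if f not in tax:
            tax.add(f, family, "family", o)
        if g not in tax:
            tax.add(g, genus, "genus", f, provisional=genus == "BVAB")
        tax.add(s, species.replace("_", " "), "species", g, provisional=provisional)
    return tax


def simulate_reference_world(
    n_taxa: int = 12,
    seqs_per_taxon: int = 5,
    seq_length: int = 300,
    seed: int = 0,
) -> ReferenceWorld:
    """Generate a reference world with guaranteed distance structure.

    Each species gets a disjoint set of signature alignment columns where
    its consensus differs from the shared ancestral sequence, so any two
    species differ at both signature sets (between-species distance
    > 0.03). Within-species copies mutate only non-signature columns,
    with a budget keeping within-species distance < 0.015.
    """
    if n_taxa < 2:
        raise ParameterError("n_taxa must be >= 2")
    if seqs_per_taxon < 1:
        raise ParameterError("seqs_per_taxon must be >= 1")
    if seq_length < 50:
        raise ParameterError("seq_length must be >= 50")
    rng = np.random.default_rng(seed)

    sig_min = max(1, math.ceil(0.016 * seq_length))
    sig = max(sig_min, math.ceil(0.05 * seq_length))
    capacity = math.floor(0.9 * seq_length)
    if n_taxa * sig > capacity:
        sig = capacity // n_taxa
    if sig < sig_min:
        raise ParameterError(
            f"cannot fit {n_taxa} taxa with distinct signatures in {seq_length} columns"
        )
    # per-sequence mutation budget: pairwise within-taxon distance <= 2w/L < 0.015
    within = math.floor(0.0074 * seq_length)

    catalog = _taxon_catalog(n_taxa)
    taxonomy = _build_taxonomy(catalog)
    root_seq = rng.choice(_BASES, size=seq_length)
    columns = rng.permutation(seq_length)
    sig_sites = {i: columns[i * sig:(i + 1) * sig] for i in range(n_taxa)}
    free_sites = columns[n_taxa * sig:]
    if within > 0 and len(free_sites) == 0:
        within = 0

    sequences: Dict[str, str] = {}
    leaf_taxids: Dict[str, str] = {}
    species_taxids: List[str] = []
    newick_clades: List[str] = []
    for i, (species, *_rest) in enumerate(catalog):
        taxid = f"s__{species}"
        species_taxids.append(taxid)
        consensus = root_seq.copy()
        for site in sig_sites[i]:
            consensus[site] = rng.choice([b for b in _BASES if b != consensus[site]])
        stem_len = sig / seq_length
        leaf_parts = []
        for j in range(seqs_per_taxon):
            seq = consensus.copy()
            if within > 0:
                sites = rng.choice(free_sites, size=within, replace=False)
                for site in sites:
                    seq[site] = rng.choice([b for b in _BASES if b != seq[site]])
            name = f"{species}_ref{j + 1}"
            sequences[name] = "".join(seq)
            leaf_taxids[name] = taxid
            tip_len = max(within / seq_length, 1e-4) * (0.8 + 0.4 * rng.random())
            leaf_parts.append(f"{name}:{tip_len:.6f}")
        if seqs_per_taxon == 1:
            newick_clades.append(f"{leaf_parts[0].split(':')[0]}:{stem_len:.6f}")
        else:
            newick_clades.append(f"({','.join(leaf_parts)}):{stem_len:.6f}")
    tree = PhyloTree.from_newick(f"({','.join(newick_clades)});")
    return ReferenceWorld(sequences, taxonomy, tree, leaf_taxids, species_taxids)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SignModel:
    """Linear model of one clinical sign on log-transformed counts.

    Latent = intercept + sum_t coef_t * (log(count_t + 0.5) - center) +
    noise; ``center`` (supplied by the cohort generator) is the log count
    of a minor taxon at the configured depth, which keeps intercepts
    meaningful across sequencing depths.
    """

    intercept: float
    coefs: Dict[str, float]          # species taxid -> coefficient
    noise_sd: float = 0.3
    thresholds: Tuple[float, ...] = (0.0,)   # cut points for discretized signs

    def latent(
        self,
        log_counts: Dict[str, float],
        rng: np.random.Generator,
        center: float = 0.0,
    ) -> float:
        x = self.intercept + sum(
            c * max(log_counts.get(t, math.log(0.5)) - center, 0.0)
            for t, c in self.coefs.items()
        )
        return x + rng.normal(0.0, self.noise_sd)


@dataclass
class EffectConfig:
    """All tunable effect sizes of the cohort generator.

    Defaults are the cohort conditions used throughout the test suite;
    build one with :meth:`default` from a reference world's species list.
    """

    species: List[str]
    dominance_concentration: float = 12.0    # Beta weight of the dominant share
    background_concentration: float = 0.4    # Dirichlet weight of the remainder
    dominant_taxa: Optional[List[str]] = None  # override the default
    # (crispatus-like / iners-like) pool of candidate dominants
    bv_log_mean: Dict[str, float] = field(default_factory=dict)
    bv_log_sigma: float = 0.8
    subgroups: List[List[str]] = field(default_factory=list)
    subgroup_loading: float = 1.4
    race_levels: List[str] = field(default_factory=lambda: ["White", "Black", "Other"])
    race_focus: str = "Black"
    race_main: Dict[str, float] = field(default_factory=dict)
    race_bv_interaction: Dict[str, float] = field(default_factory=dict)
    sign_models: Dict[str, SignModel] = field(default_factory=dict)
    zero_inflation: float = 0.12
    nb_theta: float = 2.0
    depth_mean: float = 1620.0               # mean reads per participant
    depth_cv: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ParameterError("zero_inflation must lie in [0, 1)")
        if self.nb_theta <= 0:
            raise ParameterError("nb_theta must be positive")
        seen: set = set()
        for group in self.subgroups:
            for t in group:
                if t in seen:
                    raise ParameterError(f"taxon {t} in more than one sub-group")
                seen.add(t)

    @classmethod
    def default(cls, species: Sequence[str], interaction_strength: float = 1.5) -> "EffectConfig":
        species = list(species)
        lacto = [t for t in species if "Lactobacillus" in t]
        bv_taxa = [t for t in species if t not in lacto]
        bv_log_mean = {}
        for t in species:
            if t in lacto:
                # lactobacilli are depleted in BV; L. iners less so
                bv_log_mean[t] = -1.5 if "iners" in t else -3.0
            else:
                bv_log_mean[t] = 0.0
        half = len(bv_taxa) // 2
        subgroups = [g for g in (bv_taxa[:half], bv_taxa[half:]) if len(g) >= 2]

        def pick(*fragments: str) -> List[str]:
            return [t for t in species if any(f in t for f in fragments)]

        def spread(drivers: List[str], total: float) -> Dict[str, float]:
            return {t: total / len(drivers) for t in drivers} if drivers else {}

        whiff_drivers = pick("amnionii", "Eggerthella", "BVAB1", "micraerophilus") or bv_taxa[:2]
        clue_drivers = pick("amnionii", "Eggerthella", "Gardnerella", "Atopobium") or bv_taxa[:2]
        discharge_drivers = pick("amnionii", "Eggerthella", "BVAB2") or bv_taxa[:2]
        ph_drivers = pick("amnionii", "Eggerthella", "Atopobium") or bv_taxa[:2]
        sign_models = {
            "ph": SignModel(intercept=4.0, coefs=spread(ph_drivers, 0.45),
                            noise_sd=0.18),
            "amsel_whiff": SignModel(intercept=-1.2, coefs=spread(whiff_drivers, 2.4),
                                     noise_sd=1.0),
            "clue_cells": SignModel(intercept=-1.0, coefs=spread(clue_drivers, 2.4),
                                    noise_sd=1.0, thresholds=(0.0, 2.0)),
            "amsel_discharge": SignModel(intercept=-1.2, coefs=spread(discharge_drivers, 2.2),
                                         noise_sd=1.0),
        }
        interacting = bv_taxa[: max(1, len(bv_taxa) // 3)]
        return cls(
            species=species,
            bv_log_mean=bv_log_mean,
            subgroups=subgroups,
            race_main={t: 0.3 for t in interacting},
            race_bv_interaction={t: interaction_strength for t in interacting},
            sign_models=sign_models,
        )


def _lognormal_depth(rng: np.random.Generator, mean: float, cv: float) -> int:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return max(50, int(round(rng.lognormal(mu, math.sqrt(sigma2)))))


def _zinb_counts(
    rng: np.random.Generator,
    mu: np.ndarray,
    theta: float,
    pi: float,
    protect: Optional[int] = None,
) -> np.ndarray:
    lam = rng.gamma(theta, mu / theta)
    y = rng.poisson(lam)
    zero = rng.random(len(mu)) < pi
    if protect is not None:
        # the constructed dominant taxon is present by definition
        zero[protect] = False
    y[zero] = 0
    return y


def simulate_cohort(
    n_samples: int,
    frac_bv: float,
    race_mix: Dict[str, float],
    effect: EffectConfig,
    seed: int = 0,
) -> Tuple[pd.DataFrame, CountMatrix]:
    """Simulate a cohort's metadata and sample x taxon count matrix.

    Non-BV samples draw a Lactobacillus-dominated composition (dominant
    taxon >= 50% in expectation); BV samples draw diverse compositions via
    latent-factor log-normal abundances inducing the configured sub-group
    co-occurrence. Counts follow a zero-inflated negative binomial around
    composition x depth; Nugent decreases logistically with the log
    Lactobacillus fraction; Amsel signs follow the configured sign models;
    race shifts taxon abundance with the configured main and interaction
    terms (interaction applies only in the BV state).
    """
    if not (0.0 <= frac_bv <= 1.0):
        raise ParameterError("frac_bv must lie in [0, 1]")
    if not race_mix:
        raise ParameterError("race_mix must not be empty")
    rng = np.random.default_rng(seed)
    species = effect.species
    lacto = [t for t in species if "Lactobacillus" in t]
    if effect.dominant_taxa:
        unknown = [t for t in effect.dominant_taxa if t not in species]
        if unknown:
            raise ParameterError(f"dominant_taxa not in species list: {unknown}")
        dominants = list(effect.dominant_taxa)
    else:
        dominants = [t for t in lacto if ("crispatus" in t or "iners" in t)] or lacto or species[:1]
    races = sorted(race_mix)
    probs = np.array([race_mix[r] for r in races], dtype=float)
    probs = probs / probs.sum()
    group_of = {t: g for g, group in enumerate(effect.subgroups) for t in group}

    rows = []
    counts = np.zeros((n_samples, len(species)), dtype=np.int64)
    for i in range(n_samples):
        sample_id = f"S{i + 1:04d}"
        race = races[rng.choice(len(races), p=probs)]
        is_focus = race == effect.race_focus
        bv = bool(rng.random() < frac_bv)
        if bv:
            z = rng.normal(size=max(1, len(effect.subgroups)))
            logw = np.array([
                effect.bv_log_mean.get(t, 0.0)
                + effect.bv_log_sigma * rng.normal()
                + (effect.subgroup_loading * z[group_of[t]] if t in group_of else 0.0)
                for t in species
            ])
        else:
            dom = dominants[rng.integers(len(dominants))]
            dom_idx = species.index(dom)
            # dominant share from Beta(concentration, 1), floored at 0.55 so
            # the dominant taxon always holds a majority of the composition
            share = max(0.55, float(rng.beta(effect.dominance_concentration, 1.0)))
            rest = rng.dirichlet(np.full(len(species) - 1, effect.background_concentration))
            p_vec = np.empty(len(species))
            p_vec[dom_idx] = share
            p_vec[np.arange(len(species)) != dom_idx] = (1.0 - share) * rest
            logw = np.log(p_vec + 1e-12)
        p = np.exp(logw - logw.max())
        p /= p.sum()
        depth = _lognormal_depth(rng, effect.depth_mean, effect.depth_cv)
        mu = depth * p
        if is_focus:
            # race effects act multiplicatively on expected counts, exactly
            # the log-linear mean model the ZINB regression fits; other taxa
            # stay strictly unaffected
            for t, beta in effect.race_main.items():
                mu[species.index(t)] *= math.exp(beta)
            if bv:
                for t, gamma in effect.race_bv_interaction.items():
                    mu[species.index(t)] *= math.exp(gamma)
        protect = None if bv else dom_idx
        y = _zinb_counts(rng, mu, effect.nb_theta, effect.zero_inflation,
                         protect=protect)
        while y.sum() == 0:  # included samples must have reads
            y = _zinb_counts(rng, mu, effect.nb_theta, effect.zero_inflation,
                             protect=protect)
        counts[i] = y

        total = y.sum()
        lacto_frac = y[[species.index(t) for t in lacto]].sum() / total if lacto else 0.0
        log_lf = math.log(max(lacto_frac, 1e-4))
        nugent = 10.0 / (1.0 + math.exp(2.5 * (log_lf - math.log(0.25))))
        nugent = int(np.clip(round(nugent + rng.normal(0.0, 1.0)), 0, 10))
        log_counts = {t: math.log(y[j] + 0.5) for j, t in enumerate(species)}
        # a "detectably present" log count at this depth anchors the signs
        center = math.log(0.01 * effect.depth_mean + 0.5)
        ph = effect.sign_models["ph"].latent(log_counts, rng, center)
        ph = float(round(max(3.5, ph), 2))
        whiff = int(effect.sign_models["amsel_whiff"].latent(log_counts, rng, center) > 0)
        clue_latent = effect.sign_models["clue_cells"].latent(log_counts, rng, center)
        t1, t2 = effect.sign_models["clue_cells"].thresholds
        clue = "none" if clue_latent <= t1 else ("<20%" if clue_latent <= t2 else ">20%")
        discharge = int(
            effect.sign_models["amsel_discharge"].latent(log_counts, rng, center) > 0
        )
        n_signs = discharge + int(ph > 4.5) + whiff + int(clue != "none")
        rows.append({
            "sample_id": sample_id,
            "nugent": nugent,
            "amsel_discharge": discharge,
            "ph": ph,
            "amsel_whiff": whiff,
            "clue_cells": clue,
            "bv_amsel": int(n_signs >= 3),
            "race": race,
            "bv_truth": int(bv),
        })

    meta = pd.DataFrame(rows)
    validate_sample_meta(meta)
    matrix = CountMatrix(pd.DataFrame(counts, index=meta["sample_id"], columns=species))
    return meta, matrix


# ---------------------------------------------------------------------------
# Placements
# ---------------------------------------------------------------------------

def simulate_placements(
    matrix: CountMatrix,
    world: ReferenceWorld,
    placement_spread: float = 0.0,
    seed: int = 0,
    pendant_length: float = 0.01,
) -> Dict[str, List[PlacedRead]]:
    """Simulate per-sample placed reads matching the count matrix.

    Each read deposits ``1 - placement_spread`` of its posterior mass on
    edges inside its source species' clade and the remainder on random
    edges elsewhere on the tree.
    """
    if not (0.0 <= placement_spread < 1.0):
        raise ParameterError("placement_spread must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tree = world.tree
    clade_edges: Dict[str, List[int]] = {}
    for taxid in world.species:
        leaves = world.clade_leaves(taxid)
        if not leaves:
            raise DataError(f"taxon {taxid} has no leaves on the tree")
        edges = {tree.leaf_edge(l) for l in leaves}
        if len(leaves) > 1:  # the clade's stem edge is within-taxon too
            for e in tree.edge_ids:
                if tree.leaves_below(e) <= set(leaves):
                    edges.add(e)
        clade_edges[taxid] = sorted(edges)
    all_edges = tree.edge_ids

    out: Dict[str, List[PlacedRead]] = {}
    for sample in matrix.samples:
        reads: List[PlacedRead] = []
        row = matrix.row(sample)
        for taxon, count in row.items():
            if taxon not in clade_edges:
                raise DataError(f"count matrix taxon {taxon} unknown to the tree")
            inside = clade_edges[taxon]
            outside = [e for e in all_edges if e not in inside]
            for j in range(int(count)):
                read_id = f"{sample}|{taxon}|r{j + 1}"
                n_in = 1 if len(inside) == 1 or rng.random() < 0.5 else 2
                picks = list(rng.choice(inside, size=min(n_in, len(inside)), replace=False))
                weights = list(rng.dirichlet(np.ones(len(picks))) * (1.0 - placement_spread))
                if placement_spread > 0 and outside:
                    stray = int(rng.choice(outside))
                    picks.append(stray)
                    weights.append(placement_spread)
                atts = []
                for e, w in zip(picks, weights):
                    if w <= 0:
                        continue
                    length = tree.edge_length(int(e))
                    atts.append(Attachment(
                        edge_id=int(e),
                        distal_position=float(rng.uniform(0.0, length)),
                        pendant_length=pendant_length,
                        posterior=float(w),
                    ))
                reads.append(PlacedRead(read_id, atts, sample_id=sample).normalize())
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# FASTQ runs
# ---------------------------------------------------------------------------

#: 16S portion of the reverse sequencing primer used for amplification
DEFAULT_PRIMER = "GGACTACCVGGGTATCTAAT".replace("V", "G")


def make_barcodes(samples: Sequence[str], length: int = 8, seed: int = 0) -> Dict[str, str]:
    """Random distinct fixed-length barcodes, one per sample."""
    rng = np.random.default_rng(seed)
    seen: set = set()
    out: Dict[str, str] = {}
    for s in samples:
        while True:
            bc = "".join(rng.choice(_BASES, size=length))
            if bc not in seen:
                seen.add(bc)
                out[s] = bc
                break
    return out


@dataclass
class QualityProfile:
    """Per-base Phred quality generator (Sanger Phred+33 on disk)."""

    mean: float = 38.0
    sd: float = 1.5
    low_mean: float = 18.0   # mean for injected low-quality reads

    def sample(self, n: int, rng: np.random.Generator, low: bool = False) -> List[int]:
        mean = self.low_mean if low else self.mean
        q = np.clip(np.round(rng.normal(mean, self.sd, size=n)), 2, 40)
        return [int(v) for v in q]


def write_fastq_run(
    matrix: CountMatrix,
    world: ReferenceWorld,
    barcodes: Dict[str, str],
    out_fastq,
    primer: str = DEFAULT_PRIMER,
    quality_profile: Optional[QualityProfile] = None,
    seed: int = 0,
    read_length: Tuple[int, int] = (210, 260),
    mutation_rate: float = 0.004,
    frac_bad_barcode: float = 0.0,
    frac_short: float = 0.0,
    frac_low_quality: float = 0.0,
    log_path=None,
) -> Dict[str, Dict[str, str]]:
    """Write a barcoded FASTQ run and return the injection log.

    Reads are ``barcode + primer + mutated reference subsequence``. A
    configurable fraction of deliberately failing reads (unknown barcode,
    short insert, low quality) is injected for QC testing; the log maps
    read id -> {sample, taxon, status}.
    """
    lengths = {len(b) for b in barcodes.values()}
    if len(set(barcodes.values())) != len(barcodes):
        raise ParameterError("duplicate barcodes")
    if len(lengths) != 1:
        raise ParameterError("barcodes must share one fixed length")
    missing = [s for s in matrix.samples if s not in barcodes]
    if missing:
        raise ParameterError(f"samples without barcodes: {missing}")
    qp = quality_profile or QualityProfile()
    rng = np.random.default_rng(seed)
    bc_len = lengths.pop()
    known = set(barcodes.values())
    by_taxon: Dict[str, List[str]] = {}
    for sid, taxid in world.leaf_taxids.items():
        by_taxon.setdefault(taxid, []).append(sid)

    log: Dict[str, Dict[str, str]] = {}
    records = []
    counter = 0
    for sample in matrix.samples:
        row = matrix.row(sample)
        for taxon, count in row.items():
            refs = by_taxon.get(taxon)
            if not refs:
                raise DataError(f"taxon {taxon} has no reference sequences")
            for _ in range(int(count)):
                counter += 1
                read_id = f"read{counter:07d}"
                status = "ok"
                u = rng.random()
                if u < frac_bad_barcode:
                    status = "bad_barcode"
                elif u < frac_bad_barcode + frac_short:
                    status = "short"
                elif u < frac_bad_barcode + frac_short + frac_low_quality:
                    status = "low_quality"
                ref = world.sequences[refs[rng.integers(len(refs))]].replace("-", "")
                lo, hi = read_length
                if status == "short":
                    ins_len = int(rng.integers(80, 190))
                else:
                    ins_len = int(rng.integers(lo, min(hi, len(ref)) + 1)) if len(ref) > lo else len(ref)
                start = int(rng.integers(0, max(1, len(ref) - ins_len + 1)))
                insert = np.array(list(ref[start:start + ins_len]))
                n_mut = rng.binomial(len(insert), mutation_rate)
                for site in rng.choice(len(insert), size=n_mut, replace=False):
                    insert[site] = rng.choice([b for b in _BASES if b != insert[site]])
                bc = barcodes[sample]
                if status == "bad_barcode":
                    while True:
                        bc = "".join(rng.choice(_BASES, size=bc_len))
                        if bc not in known:
                            break
                seq = bc + primer + "".join(insert)
                quals = qp.sample(len(seq), rng, low=status == "low_quality")
                rec = SeqRecord(Seq(seq), id=read_id, description="")
                rec.letter_annotations["phred_quality"] = quals
                records.append(rec)
                log[read_id] = {"sample": sample, "taxon": taxon, "status": status}
    SeqIO.write(records, out_fastq, "fastq")
    if log_path is not None:
        with open(log_path, "w") as fh:
            json.dump(log, fh, indent=1)
    return log
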