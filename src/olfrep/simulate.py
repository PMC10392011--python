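"""Synthetic data generator for the whole pipeline.

Builds, from one seeded configuration: reference receptor protein sets for
the four chemoreceptor families (OR, TAAR, V1R, V2R) plus decoy GPCR-like
proteins; multi-scaffold genomes with receptor genes planted in tandem
clusters (family-specific lengths, configurable divergence, both strands,
occasional introns, pseudogenes with premature stops, decoys); olfactory
organ expression counts with Dirichlet-distributed true proportions,
multinomial sampling and shared ambiguity classes for near-identical gene
pairs; and ultrametric pure-birth phylogenies with Brownian trait, gene
count and brain cell data.

Every output is a deterministic function of the configuration (including
its seed), so each downstream stage can be tested against known truth.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np
import pandas as pd

from ._align import (
    STOP_CODONS,
    mutate_protein,
    random_protein,
    reverse_complement,
    reverse_translate,
)

FAMILIES = ("OR", "TAAR", "V1R", "V2R")
DECOY_FAMILY = "DECOY"

#: template protein length per family; OR/TAAR/V1R templates are 320 aa and
#: V2R templates 750 aa so intact planted genes clear the 275/700 aa
#: intact-model length filters with slack.
TEMPLATE_LENGTH = {"OR": 320, "TAAR": 320, "V1R": 320, "V2R": 750, DECOY_FAMILY: 320}

#: subtype labels carried by OR references (gamma is the tetrapod-dominant
#: subtype whose proportion is reported downstream)
OR_SUBTYPES = ("gamma", "beta", "epsilon")

_GUARD_STOP = "TAA"  # in-frame stop planted 5' of each gene start codon


class SimulationCapacityError(ValueError):
    """Requested genes cannot be placed on the configured scaffolds."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all synthetic inputs.

    Defaults mirror the scale of the annotated fish data: a couple of Mb of
    receptor-bearing sequence, clusters of 6-9 genes, ~30% amino acid
    divergence from family templates, two expression replicates, and a
    24-species comparative panel.
    """

    seed: int = 0
    # genome architecture
    n_scaffolds: int = 4
    scaffold_length: int = 500_000
    clusters_per_scaffold: int = 3
    genes_per_cluster: tuple[int, int] = (6, 9)
    family_mix: dict[str, float] = field(
        default_factory=lambda: {"OR": 0.45, "TAAR": 0.25, "V1R": 0.15, "V2R": 0.15}
    )
    aa_divergence: float = 0.30
    pseudogene_rate: float = 0.10
    decoy_count: int = 10
    intron_prob: float = 0.25  # applied to V2R; other families get 1/5 of it
    intergenic_gap: tuple[int, int] = (200, 1500)
    tandem_dup_prob: float = 0.10  # near-identical recent duplicate of neighbour
    n_templates_per_family: int = 3
    # expression
    dirichlet_alpha: float = 0.8
    seq_depth: int = 100_000
    replicates: int = 2
    ambig_fraction: float = 0.30
    ambig_identity: float = 97.0
    # comparative panel
    n_species: int = 24
    beta_trait: float = 0.5
    sigma2_bm: float = 0.09
    gamma_ob: float = 0.2
    ob_noise_sd: float = 0.05
    count_intercept: float = 2.35
    sigma2_rest_brain: float = 0.04

    def __post_init__(self) -> None:
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise ValueError("family_mix must sum to 1")
        for name in ("aa_divergence", "pseudogene_rate", "intron_prob",
                     "tandem_dup_prob", "ambig_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass(frozen=True)
class RefProtein:
    id: str
    family: str
    subtype: str | None
    seq: str


@dataclass(frozen=True)
class TruthGene:
    """One planted locus; coordinates are 0-based half-open on the scaffold."""

    id: str
    family: str
    subtype: str | None
    scaffold: str
    start: int
    end: int
    strand: str
    intact: bool
    protein: str
    exons: tuple[tuple[int, int], ...]
    cluster_id: str | None = None

    @property
    def is_decoy(self) -> bool:
        return self.family == DECOY_FAMILY


@dataclass(frozen=True)
class TruthCluster:
    id: str
    scaffold: str
    members: tuple[str, ...]
    start: int
    end: int


@dataclass
class SimTruth:
    """Ground truth for recovery tests; sections fill in per stage."""

    genes: list[TruthGene] = field(default_factory=list)
    clusters: list[TruthCluster] = field(default_factory=list)
    proportions: pd.Series | None = None
    tree_newick: str | None = None
    comparative: dict | None = None

    @property
    def intact_genes(self) -> list[TruthGene]:
        return [g for g in self.genes if g.intact and not g.is_decoy]


# ---------------------------------------------------------------------------
# references


def make_references(n_per_family: int = 3, seed: int = 0) -> list[RefProtein]:
    """Generate per-family template proteins plus a decoy GPCR-like family.

    Family bases are independent random proteins (mutually far beyond the
    60% divergence requirement); templates within a family sit at ~10%
    divergence from the base. OR templates carry subtype labels so subtype
    classification can be exercised.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    rng = np.random.default_rng([seed, 101])
    refs: list[RefProtein] = []
    for family in FAMILIES + (DECOY_FAMILY,):
        base = random_protein(TEMPLATE_LENGTH[family], rng)
        for i in range(n_per_family):
            seq = mutate_protein(base, 0.10, rng)
            subtype = OR_SUBTYPES[i % len(OR_SUBTYPES)] if family == "OR" else None
            refs.append(RefProtein(f"{family}_t{i + 1}", family, subtype, seq))
    return refs


def references_by_family(refs: list[RefProtein]) -> dict[str, list[RefProtein]]:
    out: dict[str, list[RefProtein]] = {}
    for ref in refs:
        out.setdefault(ref.family, []).append(ref)
    return out


# ---------------------------------------------------------------------------
# genome planting


def _random_background(length: int, rng: np.random.Generator) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=length)].copy()


def _gene_cassette(
    protein: str,
    family: str,
    config: SimConfig,
    rng: np.random.Generator,
    pseudo: bool,
) -> tuple[str, list[tuple[int, int]], bool]:
    """Build guard-stop + CDS (optionally intron-split) in model orientation.

    Returns the cassette string, exon segments as offsets relative to the
    cassette start (guard included in the cassette, not in the exons), and
    whether an intron was inserted.
    """
    cds = reverse_translate(protein, rng) + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    if pseudo:
        n_codons = len(cds) // 3
        stop_at = int(rng.integers(int(0.3 * n_codons), int(0.6 * n_codons)))
        cds = cds[: 3 * stop_at] + "TAA" + cds[3 * stop_at + 3:]
    p_intron = config.intron_prob if family == "V2R" else config.intron_prob / 5.0
    has_intron = rng.random() < p_intron
    guard = _GUARD_STOP
    if not has_intron:
        cassette = guard + cds
        exons = [(len(guard), len(guard) + len(cds))]
        return cassette, exons, False
    n_codons = len(cds) // 3
    split = int(rng.integers(int(0.2 * n_codons), int(0.8 * n_codons)))
    intron_len = int(rng.integers(200, 2001))
    intron = "GT" + "".join(
        "ACGT"[i] for i in rng.integers(0, 4, size=intron_len - 4)
    ) + "AG"
    left, right = cds[: 3 * split], cds[3 * split:]
    cassette = guard + left + intron + right
    exons = [
        (len(guard), len(guard) + len(left)),
        (len(guard) + len(left) + len(intron), len(cassette)),
    ]
    return cassette, exons, True


def _place_cassette(
    background: np.ndarray,
    pos: int,
    cassette: str,
    exons: list[tuple[int, int]],
    strand: str,
) -> tuple[int, int, list[tuple[int, int]]]:
    """Overwrite background with the cassette; return global gene span/exons.

    The cassette is laid down forward for '+' genes and reverse-complemented
    for '-' genes; the guard stop stays 5' of the start codon on the model
    strand in both cases.
    """
    length = len(cassette)
    seq = cassette if strand == "+" else reverse_complement(cassette)
    background[pos: pos + length] = np.frombuffer(seq.encode(), dtype="S1")
    if strand == "+":
        g_exons = [(pos + s, pos + e) for s, e in exons]
    else:
        g_exons = sorted((pos + length - e, pos + length - s) for s, e in exons)
    start = min(s for s, _ in g_exons)
    end = max(e for _, e in g_exons)
    return start, end, g_exons


def plant_genome(
    config: SimConfig,
    references: list[RefProtein] | None = None,
) -> tuple[dict[str, str], SimTruth]:
    """Plant clustered receptor genes, pseudogenes and decoys on scaffolds.

    Clusters are family-homogeneous (tandem duplication produces runs of
    related genes); intra-cluster intergenic gaps come from the configured
    range, and clusters are separated by tens of kb so the truth clustering
    is unambiguous under the gap <= span/3 rule.
    """
    refs = references if references is not None else make_references(
        config.n_templates_per_family, config.seed
    )
    by_family = references_by_family(refs)
    rng = np.random.default_rng([config.seed, 202])

    # pass 1: plan cluster sizes and families so pseudogene count is exact
    families = list(config.family_mix)
    mix = np.array([config.family_mix[f] for f in families])
    plan = []  # (scaffold_index, n_genes, family)
    lo, hi = config.genes_per_cluster
    for s in range(config.n_scaffolds):
        for _ in range(config.clusters_per_scaffold):
            n_genes = int(rng.integers(lo, hi + 1))
            family = families[rng.choice(len(families), p=mix)]
            plan.append((s, n_genes, family))
    total_genes = sum(n for _, n, _ in plan)
    n_pseudo = int(round(config.pseudogene_rate * total_genes))
    pseudo_idx = set(
        rng.choice(total_genes, size=n_pseudo, replace=False).tolist()
    ) if n_pseudo else set()

    genome: dict[str, str] = {}
    truth = SimTruth()
    gene_counter = 0
    cluster_counter = 0
    plan_pos = 0
    block = config.scaffold_length // max(config.clusters_per_scaffold, 1)
    for s in range(config.n_scaffolds):
        name = f"scaf{s + 1}"
        background = _random_background(config.scaffold_length, rng)
        occupied: list[tuple[int, int]] = []
        for c in range(config.clusters_per_scaffold):
            _, n_genes, family = plan[plan_pos]
            plan_pos += 1
            cluster_counter += 1
            cluster_id = f"cl{cluster_counter}"
            cursor = block * c + int(rng.integers(block // 5, (2 * block) // 5))
            members: list[TruthGene] = []
            prev_protein: str | None = None
            for _g in range(n_genes):
                pseudo = gene_counter in pseudo_idx
                if prev_protein is not None and rng.random() < config.tandem_dup_prob:
                    protein = mutate_protein(prev_protein, 0.01, rng)
                    subtype = members[-1].subtype
                else:
                    template = by_family[family][rng.integers(len(by_family[family]))]
                    protein = mutate_protein(template.seq, config.aa_divergence, rng)
                    subtype = template.subtype
                prev_protein = protein
                cassette, exons, _ = _gene_cassette(protein, family, config, rng, pseudo)
                strand = "+" if rng.random() < 0.5 else "-"
                if cursor + len(cassette) > config.scaffold_length:
                    raise SimulationCapacityError(
                        f"scaffold {name} too short for requested clusters"
                    )
                start, end, g_exons = _place_cassette(
                    background, cursor, cassette, exons, strand
                )
                gene_counter += 1
                gene = TruthGene(
                    id=f"g{gene_counter:04d}",
                    family=family,
                    subtype=subtype,
                    scaffold=name,
                    start=start,
                    end=end,
                    strand=strand,
                    intact=not pseudo,
                    protein=protein,
                    exons=tuple(g_exons),
                    cluster_id=cluster_id,
                )
                members.append(gene)
                truth.genes.append(gene)
                occupied.append((cursor, cursor + len(cassette)))
                cursor += len(cassette) + int(
                    rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
                )
            truth.clusters.append(
                TruthCluster(
                    id=cluster_id,
                    scaffold=name,
                    members=tuple(g.id for g in members),
                    start=min(g.start for g in members),
                    end=max(g.end for g in members),
                )
            )
        # keep the mutable array and occupied spans until decoys are placed
        genome[name] = (background, occupied)

    # pass 2: decoys overwritten into free background, clear of genes
    scaffold_names = list(genome)
    decoy_refs = by_family.get(DECOY_FAMILY, [])
    for d in range(config.decoy_count):
        if not decoy_refs:
            break
        template = decoy_refs[rng.integers(len(decoy_refs))]
        protein = mutate_protein(template.seq, 0.10, rng)
        cassette, exons, _ = _gene_cassette(protein, DECOY_FAMILY, config, rng, False)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _attempt in range(200):
            name = scaffold_names[rng.integers(len(scaffold_names))]
            background, occupied = genome[name]
            pos = int(rng.integers(0, config.scaffold_length - len(cassette)))
            span = (pos - 5000, pos + len(cassette) + 5000)
            if any(a < span[1] and span[0] < b for a, b in occupied):
                continue
            start, end, g_exons = _place_cassette(background, pos, cassette, exons, strand)
            occupied.append((pos, pos + len(cassette)))
            truth.genes.append(
                TruthGene(
                    id=f"decoy{d + 1:03d}",
                    family=DECOY_FAMILY,
                    subtype=None,
                    scaffold=name,
                    start=start,
                    end=end,
                    strand=strand,
                    intact=True,
                    protein=protein,
                    exons=tuple(g_exons),
                )
            )
            placed = True
            break
        if not placed:
            raise SimulationCapacityError("could not place decoy genes")

    return {name: bg.tobytes().decode() for name, (bg, _) in genome.items()}, truth


# ---------------------------------------------------------------------------
# expression


def _near_identical_pairs(
    genes: list[TruthGene], min_identity: float
) -> list[tuple[str, str]]:
    """Gene pairs whose proteins reach the ambiguity identity threshold.

    Edit-distance identity (edlib, global mode) is a tight proxy at the
    near-identity levels relevant here.
    """
    pairs = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i].protein, genes[j].protein
            longer = max(len(a), len(b))
            if abs(len(a) - len(b)) / longer > 1 - min_identity / 100:
                continue
            dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            if 100.0 * (1 - dist / longer) >= min_identity:
                pairs.append((genes[i].id, genes[j].id))
    return pairs


def simulate_expression(
    truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate olfactory-organ counts for the planted intact genes.

    True proportions are Dirichlet(alpha)-distributed; each replicate draws
    multinomial counts at the configured depth. For every near-identical
    gene pair a shared ambiguity class receives a binomial fraction of each
    member's reads (those reads leave the unique-count table).

    Returns (unique counts table, ambiguity-class table); replicate columns
    are ``rep1..repK``. True proportions are stored on ``truth.proportions``.
    """
    genes = truth.intact_genes
    if not genes:
        raise ValueError("no intact genes to express")
    rng = np.random.default_rng([config.seed, 303])
    ids = [g.id for g in genes]
    p = rng.dirichlet(np.full(len(genes), config.dirichlet_alpha))
    truth.proportions = pd.Series(p, index=ids, name="true_proportion")

    rep_cols = [f"rep{r + 1}" for r in range(config.replicates)]
    counts = pd.DataFrame(0, index=ids, columns=rep_cols, dtype=int)
    pairs = _near_identical_pairs(genes, config.ambig_identity)
    ambig_rows = []
    for r, col in enumerate(rep_cols):
        counts[col] = rng.multinomial(config.seq_depth, p)
    for k, (a, b) in enumerate(pairs):
        row: dict[str, object] = {"class_id": f"amb{k + 1}", "members": f"{a};{b}"}
        for col in rep_cols:
            moved = 0
            for gid in (a, b):
                take = int(rng.binomial(counts.at[gid, col], config.ambig_fraction))
                counts.at[gid, col] -= take
                moved += take
            row[col] = moved
        ambig_rows.append(row)
    ambig = pd.DataFrame(
        ambig_rows, columns=["class_id", "members", *rep_cols]
    )
    return counts, ambig


# ---------------------------------------------------------------------------
# comparative panel


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Ultrametric pure-birth tree, depth rescaled to 1.

    Terminal branches are extended by 5% of the depth before rescaling so no
    tip pair is separated by a zero-length split (which would make the
    Brownian covariance singular).
    """
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_pyrandom.Random(seed),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.05 * depth
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:02d}"
    return tree


def brownian_tips(
    tree: dendropy.Tree, sigma2: float, rng: np.random.Generator
) -> pd.Series:
    """One Brownian-motion realisation; returns tip values keyed by taxon."""
    values: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = values.get(node.parent_node, 0.0)
        edge = node.edge.length or 0.0
        values[node] = parent + (
            rng.normal(0.0, np.sqrt(sigma2 * edge)) if edge > 0 and sigma2 > 0 else 0.0
        )
    return pd.Series(
        {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    ).sort_index()


def _pick_trait_clade(
    tree: dendropy.Tree, rng: np.random.Generator
) -> list[str]:
    """A clade covering 20-40% of tips (closest available if none fits)."""
    n = len(tree.taxon_namespace)
    candidates = []
    for node in tree.preorder_internal_node_iter():
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if len(tips) < n:
            candidates.append(tips)
    in_band = [t for t in candidates if 0.2 * n <= len(t) <= 0.4 * n]
    pool = in_band or sorted(
        candidates, key=lambda t: abs(len(t) - 0.3 * n)
    )[:1]
    return pool[int(rng.integers(len(pool)))]


def simulate_comparative(
    config: SimConfig,
) -> tuple[dendropy.Tree, pd.DataFrame, SimTruth]:
    """Simulate the species panel behind the comparative tests.

    A random clade carries the freshwater+amphibious+nocturnal (FAN)
    phenotype; log10 gene counts evolve by Brownian motion with an additive
    trait effect; log10 olfactory-bulb cells respond to rest-of-brain size
    and gene counts with Gaussian noise.
    """
    if config.n_species < 4:
        raise ValueError("n_species must be >= 4")
    rng = np.random.default_rng([config.seed, 404])
    tree = simulate_tree(config.n_species, seed=int(rng.integers(2**31 - 1)))
    species = sorted(t.label for t in tree.taxon_namespace)
    clade = set(_pick_trait_clade(tree, rng))
    trait = pd.Series({sp: float(sp in clade) for sp in species}).sort_index()

    bm = brownian_tips(tree, config.sigma2_bm, rng)
    log_counts = config.count_intercept + bm + config.beta_trait * trait
    log_rest = 8.0 + brownian_tips(tree, config.sigma2_rest_brain, rng)
    log_ob = (
        -2.0
        + 1.0 * log_rest
        + config.gamma_ob * log_counts
        + rng.normal(0.0, config.ob_noise_sd, size=len(species))
    )

    families = list(SimConfig().family_mix)
    mix = np.array([SimConfig().family_mix[f] for f in families])
    log_ob = pd.Series(log_ob, index=species)
    rows = []
    for i, sp in enumerate(species):
        fan = sp in clade
        total = max(int(round(10 ** log_counts[sp])), 4)
        fam_counts = np.maximum(np.round(total * mix).astype(int), 1)
        rows.append(
            {
                "species": sp,
                "salinity": "freshwater" if fan else
                ["marine", "freshwater", "brackish"][
                    rng.choice(3, p=[0.55, 0.35, 0.10])
                ],
                "habitat_zone": ["pelagic", "benthic", "benthopelagic",
                                 "reef-associated"][rng.integers(4)],
                "diadromous": bool(rng.random() < 0.1),
                "amphibious": fan,
                "activity": "nocturnal" if fan else
                ["nocturnal", "diurnal", "arrhythmic", "unknown"][
                    rng.choice(4, p=[0.25, 0.50, 0.15, 0.10])
                ],
                "land_exploration": fan,
                "olf_total": total,
                **{f"olf_{fam}": int(c) for fam, c in zip(families, fam_counts)},
                "ob_cells": int(round(10 ** log_ob[sp])),
                "rest_brain_cells": int(round(10 ** log_rest[sp])),
            }
        )
    traits = pd.DataFrame(rows).set_index("species")
    truth = SimTruth(
        tree_newick=tree.as_string(schema="newick", suppress_rooting=True).strip(),
        comparative={
            "beta_trait": config.beta_trait,
            "sigma2_bm": config.sigma2_bm,
            "gamma_ob": config.gamma_ob,
            "fan_species": sorted(clade),
            "log10_counts": log_counts,
            "log10_ob": log_ob,
            "log10_rest": log_rest,
        },
    )
    return tree, traits, truth


def small_config(seed: int = 0) -> SimConfig:
    """A compact configuration for quick end-to-end runs."""
    return SimConfig(
        seed=seed,
        n_scaffolds=2,
        scaffold_length=250_000,
        clusters_per_scaffold=2,
        genes_per_cluster=(5, 6),
        decoy_count=4,
        seq_depth=50_000,
        n_species=16,
    )


def recovery_config(seed: int = 0) -> SimConfig:
    """The 2 Mb recovery benchmark: 90 planted receptors (10 pseudogenes),
    20 decoys, 30% amino acid divergence."""
    return SimConfig(
        seed=seed,
        n_scaffolds=5,
        scaffold_length=400_000,
        clusters_per_scaffold=2,
        genes_per_cluster=(9, 9),
        pseudogene_rate=1.0 / 9.0,
        decoy_count=20,
        aa_divergence=0.30,
    )
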