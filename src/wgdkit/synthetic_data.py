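"""Simulators with known truth for every stage of the WGD pipeline.

Three generators are provided:

* :func:`simulate_wgd_genome` — gene families produced by 0-3 layered
  whole-genome duplications at chosen corrected-4DTv depths, with
  per-event retention, neutral evolution of four-fold-degenerate third
  positions under a two-parameter (transition/transversion) process,
  injected tandem arrays and single-copy decoy genes.
* :func:`simulate_kmer_histogram` — diploid k-mer copy-number spectra with
  heterozygous and homozygous modes and a sequencing-error spike.
* :func:`simulate_contig_set` — contig sets containing near-identical
  duplicate (heterozygous) contigs and terminal overlaps between
  consecutive fragments.

Depth calibration
-----------------
A pair of paralogs "split at depth d" means the expected *corrected* 4DTv
between them is d.  Under the two-parameter process with transition rate
kappa*beta and two transversion targets at rate beta each, the probability
that two sequences separated by total path time T differ by a transversion
at a site is q = (1 - exp(-4*beta*T)) / 2, and the multiple-hit correction
-1/2 ln(1 - 2q) returns 2*beta*T exactly.  The simulator therefore evolves
each pair over a total path of beta*T = d/2 (d/4 per lineage), so the
estimator and simulator are mutually calibrated: E[raw 4DTv] =
(1 - exp(-2d))/2 and the corrected statistic recovers d.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np

from .model import Contig, GeneModel, KmerHistogram, assign_ranks

# base encoding: A=0, G=1, C=2, T=3 (purines first, so transition partner = base ^ 1)
BASES = "AGCT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

FOURFOLD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)

_CODON_TABLE = {}


def _codon_to_aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in SENSE_CODONS:
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


def k80_substitution_probs(beta_t: float, kappa: float) -> Tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after scaled time beta*t."""
    e4 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * beta_t * (kappa + 1.0))
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return float(p_same), float(p_ts), float(p_tv)


def evolve_bases(bases: np.ndarray, beta_t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an int-encoded base array for scaled time beta*t under K80."""
    if beta_t == 0.0 or bases.size == 0:
        return bases.copy()
    p_same, p_ts, p_tv = k80_substitution_probs(beta_t, kappa)
    u = rng.random(bases.shape)
    out = bases.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = bases[ts] ^ 1
    out[tv1] = (bases[tv1] + 2) % 4
    out[tv2] = ((bases[tv2] + 2) % 4) ^ 1
    return out


def simulate_divergent_site_pair(
    depth: float, n_sites: int, kappa: float, rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """Simulate third-position base pairs for a paralog pair split at *depth*.

    Returns a list of (base_a, base_b) site pairs ready for
    :func:`wgdkit.fourdtv.fourdtv_statistic`.
    """
    _check_depth(depth)
    anc = rng.integers(0, 4, size=n_sites)
    a = evolve_bases(anc, depth / 4.0, kappa, rng)
    b = evolve_bases(anc, depth / 4.0, kappa, rng)
    return [(BASES[x], BASES[y]) for x, y in zip(a, b)]


def _check_depth(depth: float) -> None:
    if not np.isfinite(depth) or depth <= 0:
        raise ValueError(f"WGD depth must be finite and positive, got {depth}")
    # expected uncorrected 4DTv must stay below the 0.5 saturation bound
    if (1.0 - np.exp(-2.0 * depth)) / 2.0 >= 0.5:
        raise ValueError(f"depth {depth} saturates the uncorrected 4DTv scale")


@dataclass(frozen=True)
class WGDSimConfig:
    """Scenario description for a simulated genome with layered WGDs.

    ``wgd_depths`` are expected corrected-4DTv divergences, oldest event
    first (strictly decreasing toward the present).  ``retention_prob`` is
    the per-event, per-gene probability that the new duplicate survives.
    ``cds_length_codons`` defaults to 450 (a ~1.35 kb CDS, typical of
    arthropod gene models), giving a pair roughly 220 four-fold-degenerate
    sites and corrected-4DTv peak widths of the same order as real paralog
    age distributions.
    """

    n_ancestral_genes: int = 400
    n_chromosomes: int = 4
    wgd_depths: Tuple[float, ...] = (1.33, 0.85, 0.40)
    retention_prob: float = 0.6
    kappa: float = 2.0
    cds_length_codons: int = 450
    tandem_arrays: Tuple[Tuple[int, float], ...] = ()
    intergenic_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one gene and one chromosome")
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for d in self.wgd_depths:
            _check_depth(d)
        if any(b >= a for a, b in zip(self.wgd_depths, self.wgd_depths[1:])):
            raise ValueError("wgd_depths must be strictly decreasing (oldest first)")
        for size, identity in self.tandem_arrays:
            if size < 2 or not 0.0 < identity <= 1.0:
                raise ValueError("tandem arrays need size >= 2 and identity in (0, 1]")


@dataclass
class SimulatedGenome:
    """A simulated annotation plus the truth every downstream stage is tested against."""

    genes: List[GeneModel]
    truth_families: Dict[str, List[str]]
    truth_pair_depths: Dict[FrozenSet[str], float]
    truth_tandem_clusters: List[List[str]]
    config: WGDSimConfig = None


def _random_cds(n_codons: int, rng: np.random.Generator) -> List[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def _translate(codons: Sequence[str]) -> str:
    return "".join(_codon_to_aa(c) for c in codons)


def _existing_paths(
    n_events: int, retention: float, rng: np.random.Generator
) -> List[Tuple[int, ...]]:
    """Enumerate surviving copy lineages through the WGD cascade.

    A lineage is a bit per event: 0 = stayed on the parental chromosome copy,
    1 = descended to the new copy.  The parental copy always survives; each
    new duplicate survives with probability *retention*.
    """
    paths: List[Tuple[int, ...]] = [()]
    for _ in range(n_events):
        nxt: List[Tuple[int, ...]] = []
        for p in paths:
            nxt.append(p + (0,))
            if rng.random() < retention:
                nxt.append(p + (1,))
        paths = nxt
    return paths


def _evolve_family(
    anc_bases: np.ndarray,
    paths: List[Tuple[int, ...]],
    depths: Sequence[float],
    kappa: float,
    rng: np.random.Generator,
) -> Dict[Tuple[int, ...], np.ndarray]:
    """Evolve 4D third positions along the duplication tree of one family.

    A pair split at depth d must accumulate total path length beta*T = d/2
    (so that the corrected transversion distance 2*beta*T equals d); on the
    per-lineage clock a WGD at depth d therefore sits at scaled time d/4
    before the present, and branches between consecutive events span
    (d_prev - d_next)/4.
    """
    current: Dict[Tuple[int, ...], np.ndarray] = {(): anc_bases}
    for i, d in enumerate(depths):
        if i > 0:
            dt = (depths[i - 1] - d) / 4.0
            current = {p: evolve_bases(b, dt, kappa, rng) for p, b in current.items()}
        nxt: Dict[Tuple[int, ...], np.ndarray] = {}
        for p, b in current.items():
            for bit in (0, 1):
                child = p + (bit,)
                if any(fp[: len(child)] == child for fp in paths):
                    nxt[child] = b.copy()
        current = nxt
    if depths:
        dt = depths[-1] / 4.0
        current = {p: evolve_bases(b, dt, kappa, rng) for p, b in current.items()}
    return current


def pair_depth(path_a: Tuple[int, ...], path_b: Tuple[int, ...], depths: Sequence[float]) -> float:
    """Expected corrected 4DTv between two lineages = depth of the first split."""
    for i, (x, y) in enumerate(zip(path_a, path_b)):
        if x != y:
            return depths[i]
    raise ValueError("identical lineages have no divergence depth")


def simulate_wgd_genome(config: WGDSimConfig) -> SimulatedGenome:
    """Simulate a genome whose paralog families arose from layered WGDs."""
    rng = np.random.default_rng(config.seed)
    depths = list(config.wgd_depths)
    n_events = len(depths)

    # per-chromosome gene order: (sort_key, GeneModel without coordinates yet)
    chrom_layout: Dict[str, List[GeneModel]] = {}
    truth_families: Dict[str, List[str]] = {}
    truth_pair_depths: Dict[FrozenSet[str], float] = {}
    truth_tandem: List[List[str]] = []

    def chrom_name(base: int, path: Tuple[int, ...]) -> str:
        if not path:
            return f"chr{base + 1}"
        return f"chr{base + 1}_" + "".join(str(b) for b in path)

    for gi in range(config.n_ancestral_genes):
        base_chrom = gi % config.n_chromosomes
        codons = _random_cds(config.cds_length_codons, rng)
        protein = _translate(codons)
        fourfold_pos = np.array(
            [i for i, c in enumerate(codons) if c[:2] in FOURFOLD_PREFIXES], dtype=int
        )
        anc_bases = np.array([BASE_INDEX[codons[i][2]] for i in fourfold_pos], dtype=np.int64)

        paths = _existing_paths(n_events, config.retention_prob, rng)
        evolved = _evolve_family(anc_bases, paths, depths, config.kappa, rng)

        fam_id = f"fam{gi:04d}"
        members = []
        member_paths = {}
        for path in paths:
            tag = "".join(str(b) for b in path) if path else "anc"
            gene_id = f"g{gi:04d}_{tag}"
            bases = evolved[path]
            gene_codons = list(codons)
            for pos, b in zip(fourfold_pos, bases):
                gene_codons[pos] = gene_codons[pos][:2] + BASES[b]
            gene = GeneModel(
                gene_id=gene_id,
                chromosome=chrom_name(base_chrom, path),
                start=0,
                end=1,  # placeholder; coordinates laid out below
                strand="+" if rng.random() < 0.5 else "-",
                name=f"family {gi:04d} protein",
                protein=protein,
                cds="".join(gene_codons),
            )
            chrom_layout.setdefault(gene.chromosome, []).append(gene)
            members.append(gene_id)
            member_paths[gene_id] = path
        truth_families[fam_id] = members
        for a, b in itertools.combinations(members, 2):
            truth_pair_depths[frozenset((a, b))] = pair_depth(
                member_paths[a], member_paths[b], depths
            )

    chrom_names = sorted(chrom_layout)

    # single-copy decoy genes sprinkled across chromosomes
    for di in range(config.intergenic_genes):
        codons = _random_cds(max(config.cds_length_codons // 3, 60), rng)
        gene = GeneModel(
            gene_id=f"decoy{di:04d}",
            chromosome=chrom_names[int(rng.integers(0, len(chrom_names)))],
            start=0,
            end=1,
            strand="+" if rng.random() < 0.5 else "-",
            name=f"decoy {di:04d} protein",
            protein=_translate(codons),
            cds="".join(codons),
        )
        members = chrom_layout[gene.chromosome]
        members.insert(int(rng.integers(0, len(members) + 1)), gene)
        truth_families[f"decoyfam{di:04d}"] = [gene.gene_id]

    # tandem arrays: adjacent same-name copies mutated from one template
    for ti, (size, identity_target) in enumerate(config.tandem_arrays):
        n_codons = max(config.cds_length_codons // 3, 60)
        template = _random_cds(n_codons, rng)
        per_copy_rate = (1.0 - identity_target) / 2.0
        array_genes = []
        for ci in range(size):
            codons = list(template)
            hit = rng.random(n_codons) < per_copy_rate
            for pos in np.flatnonzero(hit):
                aa_old = _codon_to_aa(codons[pos])
                choices = [c for c in SENSE_CODONS if _codon_to_aa(c) != aa_old]
                codons[pos] = choices[int(rng.integers(0, len(choices)))]
            gene = GeneModel(
                gene_id=f"tnd{ti:02d}_{ci:02d}",
                chromosome="",  # set below
                start=0,
                end=1,
                strand="+",
                name=f"tandem {ti:02d} protein",
                protein=_translate(codons),
                cds="".join(codons),
            )
            array_genes.append(gene)
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        insert_at = int(rng.integers(0, len(chrom_layout[chrom]) + 1))
        for offset, gene in enumerate(array_genes):
            gene.chromosome = chrom
            chrom_layout[chrom].insert(insert_at + offset, gene)
        ids = [g.gene_id for g in array_genes]
        truth_tandem.append(ids)
        truth_families[f"tndfam{ti:02d}"] = ids
        for a, b in itertools.combinations(ids, 2):
            truth_pair_depths[frozenset((a, b))] = 0.0

    # lay out coordinates chromosome by chromosome
    genes: List[GeneModel] = []
    for chrom in chrom_names:
        cursor = 0
        for gene in chrom_layout[chrom]:
            spacing = int(rng.integers(200, 1000))
            gene.start = cursor
            gene.end = cursor + len(gene.cds)
            cursor = gene.end + spacing
            genes.append(gene)
    assign_ranks(genes)
    return SimulatedGenome(
        genes=genes,
        truth_families=truth_families,
        truth_pair_depths=truth_pair_depths,
        truth_tandem_clusters=truth_tandem,
        config=config,
    )


def simulate_kmer_histogram(
    genome_size: int,
    coverage: float,
    read_len: int = 150,
    k: int = 31,
    heterozygosity: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[KmerHistogram, Dict[str, float]]:
    """Simulate a diploid k-mer copy-number spectrum.

    Homozygous k-mers sit at Poisson(c) with c = coverage*(L-k+1)/L; each
    heterozygous site converts k homozygous k-mers into 2k haplotype-specific
    k-mers at depth c/2; sequencing errors add a spike decaying from KCN = 1.
    Returns the histogram and a truth dict with the genome size and k-mer
    depth c.
    """
    if k > read_len:
        raise ValueError("k must not exceed the read length")
    if coverage <= 0 or genome_size <= 0:
        raise ValueError("coverage and genome size must be positive")
    rng = np.random.default_rng(seed)
    c = coverage * (read_len - k + 1) / read_len

    n_het = int(round(genome_size * heterozygosity * 2 * k))
    n_hom = genome_size - int(round(genome_size * heterozygosity * k))
    if n_hom <= 0:
        raise ValueError("heterozygosity too high for this genome size and k")

    counts = np.zeros(0, dtype=np.int64)

    def _acc(values: np.ndarray) -> None:
        nonlocal counts
        if values.size == 0:
            return
        binned = np.bincount(values[values > 0])
        if binned.size > counts.size:
            binned[: counts.size] += counts
            counts = binned
        else:
            counts[: binned.size] += binned

    _acc(rng.poisson(c, size=n_hom))
    if n_het:
        _acc(rng.poisson(c / 2.0, size=n_het))
    if error_rate > 0:
        n_err_instances = genome_size * coverage * error_rate * k
        n_err_distinct = int(n_err_instances / 1.25)  # geometric(0.8) mean
        _acc(rng.geometric(0.8, size=n_err_distinct).astype(np.int64))

    entries = tuple((kcn, int(n)) for kcn, n in enumerate(counts) if kcn >= 1)
    hist = KmerHistogram(k=k, entries=entries)
    return hist, {"genome_size": float(genome_size), "kmer_depth": c}


@dataclass
class ContigSetTruth:
    """Expected curation outcome for a simulated contig set."""

    removed: Set[str]
    merge_groups: List[FrozenSet[str]]
    final_n_contigs: int
    final_total_length: int


def simulate_contig_set(
    genome_length: int,
    n_duplicates: int,
    overlap_lengths: Sequence[int],
    identity_noise: float,
    seed: int = 0,
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
    min_overlap: int = 30000,
) -> Tuple[List[Contig], ContigSetTruth]:
    """Cut a random genome into overlapping fragments plus noisy duplicates.

    Consecutive fragments share the requested exact terminal overlaps;
    ``n_duplicates`` full copies of randomly chosen fragments are appended
    with substitution noise at rate *identity_noise*.  The truth records
    which contigs the curation thresholds (given here so that tests can
    scale them down) should remove or merge.
    """
    rng = np.random.default_rng(seed)
    n_frags = len(overlap_lengths) + 1
    bounds = np.linspace(0, genome_length, n_frags + 1).astype(int)
    seg_lengths = np.diff(bounds)
    for i, ov in enumerate(overlap_lengths):
        if ov <= 0 or ov >= seg_lengths[i] or ov >= seg_lengths[i + 1]:
            raise ValueError(f"overlap {ov} infeasible for the fragment layout")

    genome = "".join(BASES[i] for i in rng.integers(0, 4, size=genome_length))
    contigs: List[Contig] = []
    for i in range(n_frags):
        start = bounds[i]
        end = bounds[i + 1] + (overlap_lengths[i] if i < n_frags - 1 else 0)
        contigs.append(Contig(f"ctg{i:02d}", genome[start:end]))

    removed: Set[str] = set()
    dup_sources = rng.integers(0, n_frags, size=n_duplicates)
    for j, src in enumerate(dup_sources):
        seq = list(contigs[src].sequence)
        if identity_noise > 0:
            hit = rng.random(len(seq)) < identity_noise
            for pos in np.flatnonzero(hit):
                alternatives = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = alternatives[int(rng.integers(0, 3))]
        dup_id = f"{contigs[src].contig_id}_dup{j}"
        contigs.append(Contig(dup_id, "".join(seq)))
        expected_identity = 1.0 - identity_noise
        if expected_identity >= min_identity and 1.0 >= min_coverage:
            removed.add(dup_id)  # full-length copy: coverage 1, lex-later id

    # merge chains among surviving fragments: consecutive overlaps above threshold
    merge_groups: List[FrozenSet[str]] = []
    group = [contigs[0].contig_id]
    for i, ov in enumerate(overlap_lengths):
        if ov > min_overlap:
            group.append(contigs[i + 1].contig_id)
        else:
            if len(group) > 1:
                merge_groups.append(frozenset(group))
            group = [contigs[i + 1].contig_id]
    if len(group) > 1:
        merge_groups.append(frozenset(group))

    n_merged_away = sum(len(g) - 1 for g in merge_groups)
    final_n = len(contigs) - len(removed) - n_merged_away
    surviving_len = sum(len(ctg) for ctg in contigs if ctg.contig_id not in removed)
    overlap_loss = sum(
        ov for i, ov in enumerate(overlap_lengths) if ov > min_overlap
    )
    truth = ContigSetTruth(
        removed=removed,
        merge_groups=merge_groups,
        final_n_contigs=final_n,
        final_total_length=surviving_len - overlap_loss,
    )
    return contigs, truth
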