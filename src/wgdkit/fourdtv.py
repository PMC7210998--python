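"""The corrected 4DTv statistic for paralog pairs.

Pipeline per pair: global protein alignment, back-translation of the
protein alignment to a codon alignment, extraction of four-fold-degenerate
(4D) sites (both codons share an identical dinucleotide prefix belonging to
a 4-fold codon family), transversion counting, and the multiple-hit
correction

    4DTv_corrected = -1/2 ln(1 - 2 * 4DTv_raw),

which equals the transversion distance of a two-parameter substitution
model and is defined only while the raw fraction stays below the 0.5
saturation bound.  Pairs with fewer than 30 4D sites are flagged as
failing the retention filter.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
from Bio.Seq import Seq

from ._align import align_protein_pair
from .model import FourDTvRecord, GeneModel
from .paralog_families import ParalogFamily

FOURFOLD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

GAP_CODON = "---"

_CODON_TO_AA: Dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    if not _CODON_TO_AA:
        bases = "TCAG"
        for c in ("".join(t) for t in itertools.product(bases, repeat=3)):
            _CODON_TO_AA[c] = str(Seq(c).translate())
    return _CODON_TO_AA.get(codon, "X")


@dataclass(frozen=True)
class CodonPairAlignment:
    """Aligned codon columns of two CDSs, induced by a protein alignment."""

    id_a: str
    id_b: str
    codons_a: Tuple[str, ...]
    codons_b: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignments must have equal column counts")


def backtranslate_to_codons(
    protein_alignment: Tuple[str, str],
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonPairAlignment:
    """Map a gapped protein alignment onto the underlying codons.

    Each aligned residue column becomes its source codon; residue gaps
    become the gap codon ``---``.  The CDSs must translate exactly to the
    ungapped proteins (a trailing stop codon is tolerated and dropped).
    """
    ga, gb = protein_alignment
    if len(ga) != len(gb):
        raise ValueError("gapped protein strings must have equal length")
    cds_a = _strip_stop(cds_a, ga.replace("-", ""), id_a)
    cds_b = _strip_stop(cds_b, gb.replace("-", ""), id_b)
    cols_a = _thread_codons(ga, cds_a, id_a)
    cols_b = _thread_codons(gb, cds_b, id_b)
    return CodonPairAlignment(id_a=id_a, id_b=id_b, codons_a=tuple(cols_a), codons_b=tuple(cols_b))


def _strip_stop(cds: str, protein: str, label: str) -> str:
    if len(cds) == 3 * (len(protein) + 1) and cds[-3:].upper() in ("TAA", "TAG", "TGA"):
        cds = cds[:-3]
    if len(cds) != 3 * len(protein):
        raise ValueError(
            f"{label}: CDS length {len(cds)} does not match {len(protein)} aligned residues"
        )
    return cds.upper()


def _thread_codons(gapped: str, cds: str, label: str) -> List[str]:
    cols = []
    pos = 0
    for i, residue in enumerate(gapped):
        if residue == "-":
            cols.append(GAP_CODON)
            continue
        codon = cds[3 * pos : 3 * pos + 3]
        translated = _translate_codon(codon)
        if translated != residue:
            raise ValueError(
                f"{label}: codon {codon} at position {pos} translates to "
                f"{translated}, alignment has {residue}"
            )
        cols.append(codon)
        pos += 1
    return cols


def extract_4d_sites(aln: CodonPairAlignment) -> List[Tuple[str, str]]:
    """Third-position base pairs at shared four-fold-degenerate codons.

    A column yields a site iff neither codon is a gap, the two codons'
    first two bases are identical, and that prefix belongs to a 4-fold
    codon family.  Requiring prefix identity is deliberate: a prefix change
    alters the degeneracy class, so such columns are not comparable.
    """
    sites = []
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            sites.append((ca[2], cb[2]))
    return sites


def is_transversion(base_a: str, base_b: str) -> bool:
    return (base_a in PURINES and base_b in PYRIMIDINES) or (
        base_a in PYRIMIDINES and base_b in PURINES
    )


def correct_fourdtv(raw: float) -> Optional[float]:
    """Multiple-hit correction -1/2 ln(1 - 2x); None when saturated (x >= 1/2)."""
    if raw >= 0.5:
        return None
    return -0.5 * math.log1p(-2.0 * raw)


def fourdtv_statistic(
    sites: Sequence[Tuple[str, str]],
    min_sites: int = 30,
    id_a: str = "a",
    id_b: str = "b",
) -> FourDTvRecord:
    """Raw and corrected 4DTv from a list of 4D-site base pairs."""
    n = len(sites)
    tv = sum(1 for a, b in sites if is_transversion(a, b))
    raw = tv / n if n else 0.0
    corrected = correct_fourdtv(raw)
    return FourDTvRecord(
        id_a=id_a,
        id_b=id_b,
        n_4d_sites=n,
        n_transversions=tv,
        fourdtv_raw=raw,
        fourdtv_corrected=corrected,
        passes_filter=(n >= min_sites and corrected is not None),
    )


def pair_fourdtv(
    id_a: str,
    id_b: str,
    protein_a: str,
    protein_b: str,
    cds_a: str,
    cds_b: str,
    min_sites: int = 30,
) -> FourDTvRecord:
    """Full per-pair pipeline: align, back-translate, extract, count, correct."""
    aligned = align_protein_pair(protein_a, protein_b)
    codon_aln = backtranslate_to_codons(aligned, cds_a, cds_b, id_a, id_b)
    return fourdtv_statistic(extract_4d_sites(codon_aln), min_sites, id_a, id_b)


def family_fourdtv(
    families: Iterable[ParalogFamily],
    genes: Sequence[GeneModel],
    min_sites: int = 30,
    representatives_only: bool = False,
) -> List[FourDTvRecord]:
    """Score all unordered member pairs of each family.

    ``representatives_only`` restricts scoring to post-tandem-collapse
    representatives.  Pairs missing a protein or CDS sequence are skipped.
    """
    lookup: Dict[str, GeneModel] = {g.gene_id: g for g in genes}
    records = []
    for family in families:
        ids = family.representatives if representatives_only else family.members
        for id_a, id_b in itertools.combinations(sorted(ids), 2):
            ga, gb = lookup.get(id_a), lookup.get(id_b)
            if not ga or not gb or not ga.protein or not gb.protein or not ga.cds or not gb.cds:
                continue
            records.append(
                pair_fourdtv(id_a, id_b, ga.protein, gb.protein, ga.cds, gb.cds, min_sites)
            )
    return records


def neutral_rate_from_tree(
    tree, taxon_a: str, taxon_b: str, divergence_time: float
) -> float:
    """Neutral substitution rate from a calibrated tree.

    rate = patristic path length between the two leaves / (2 * divergence_time),
    with the divergence time in years and branch lengths in
    substitutions/site.
    """
    if divergence_time <= 0:
        raise ValueError("divergence time must be positive")
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if os.path.exists(text):
            t = dendropy.Tree.get(path=text, schema="newick")
        else:
            t = dendropy.Tree.get(data=text, schema="newick")
    labels = {leaf.taxon.label for leaf in t.leaf_node_iter() if leaf.taxon}
    for taxon in (taxon_a, taxon_b):
        if taxon not in labels:
            raise ValueError(f"taxon {taxon!r} not found in tree")
    pdm = t.phylogenetic_distance_matrix()
    namespace = t.taxon_namespace
    dist = pdm.patristic_distance(
        namespace.get_taxon(taxon_a), namespace.get_taxon(taxon_b)
    )
    return dist / (2.0 * divergence_time)
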