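"""Phosphomimetic C-terminal display-library design.

Builds a combinatorial wild-type / phosphomimetic (Ser/Thr→Glu) peptide
library from a proteome and a phosphosite annotation table.  The unit of
design is the unique C-terminal 9-mer; every annotated Ser/Thr phosphosite
within those last nine residues spawns phosphomimetic variants, including
all combinations when a C-terminus carries several sites.

Coordinates are C-anchored throughout: p0 is the C-terminal residue and
p-k lies k residues upstream.  A site at 1-based protein position q in a
protein of length n has p-index ``q - n``.

PDZ-binding-motif (PDZbm) classes are read off the last three residues:
class I S/T-x-Φ, class II Φ-x-Φ, class III D/E-x-Φ, where Φ is a
configurable hydrophobic alphabet and only p0 and p-2 are inspected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .codons import RANKED_CODONS, TOP_CODON, reverse_translate, translate

logger = logging.getLogger(__name__)

DEFAULT_PHI = frozenset("AVILMFWYC")
#: annealing flanks joining the insert to the display phagemid; the 3'
#: flank opens with tandem stops so the displayed peptide ends at p0
DEFAULT_FLANK5 = "GGCGGTTCTGGTGGC"
DEFAULT_FLANK3 = "TAATGAGGTGGCGGT"
SMAI_SITE = "CCCGGG"

CLASS_I = "classI"
CLASS_II = "classII"
CLASS_III = "classIII"
CLASS_NONE = "none"


class DesignError(ValueError):
    """Raised for infeasible or inconsistent design inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or any(c.isspace() for c in self.sequence):
            raise DesignError(f"{self.protein_id}: empty or whitespace-containing sequence")
        if "*" in self.sequence:
            raise DesignError(f"{self.protein_id}: stop character in sequence")


@dataclass(frozen=True)
class PhosphositeAnnotation:
    """One annotated Ser/Thr phosphosite (1-based protein coordinates)."""

    protein_id: str
    position: int
    residue: str
    source: str = "known"
    kinase: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T"):
            raise DesignError(
                f"{self.protein_id}:{self.position}: residue {self.residue!r} is not S/T"
            )


@dataclass(frozen=True)
class CTermPeptide:
    """A unique C-terminal L-mer with its phosphosites in p-coordinates.

    ``kinases`` maps a p-index to the sorted kinase labels annotated for
    the site (possibly empty).
    """

    aa_seq: str
    site_positions: frozenset[int]
    source_proteins: frozenset[str]
    kinases: tuple[tuple[int, tuple[str, ...]], ...] = ()

    @property
    def peptide_id(self) -> str:
        return self.aa_seq

    @property
    def length(self) -> int:
        return len(self.aa_seq)

    def residue_at(self, p: int) -> str:
        """Residue at C-anchored position p (p0 = last)."""
        return self.aa_seq[len(self.aa_seq) - 1 + p]


@dataclass(frozen=True)
class LibraryEntry:
    """One displayable variant: wild type or a specific S/T→E combination."""

    entry_id: str
    peptide: CTermPeptide
    mimetic_mask: frozenset[int]
    aa_seq: str
    nt_seq: str = ""
    oligo: str = ""

    @property
    def is_wild_type(self) -> bool:
        return not self.mimetic_mask


@dataclass(frozen=True)
class DesignConfig:
    L: int = 9
    mimetic_residue: str = "E"
    phi_set: frozenset[str] = DEFAULT_PHI
    codon_table: dict[str, str] = field(default_factory=lambda: dict(TOP_CODON))
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    forbidden_sites: tuple[str, ...] = (SMAI_SITE,)
    max_sites: int = 8

    def __post_init__(self) -> None:
        if self.phi_set & set("STDE"):
            raise DesignError("phi_set must be disjoint from {S,T,D,E} for exclusive classes")
        for fl in (self.flank5, self.flank3):
            if set(fl) - set("ACGT"):
                raise DesignError(f"flank {fl!r} contains non-ACGT characters")


def mask_to_str(mask: frozenset[int]) -> str:
    return "wt" if not mask else ",".join(str(p) for p in sorted(mask))


def classify_pdzbm(aa_seq: str, phi_set: frozenset[str] = DEFAULT_PHI) -> str:
    """Classify the C-terminal PDZ-binding motif of a peptide.

    Only p0 and p-2 are inspected; a hydrophobic p0 is required for any
    class.  Returns one of ``classI``/``classII``/``classIII``/``none``.
    """
    if len(aa_seq) < 3:
        raise DesignError(f"need >= 3 residues to classify, got {aa_seq!r}")
    p0, pm2 = aa_seq[-1], aa_seq[-3]
    if p0 not in phi_set:
        return CLASS_NONE
    if pm2 in ("S", "T"):
        return CLASS_I
    if pm2 in phi_set:
        return CLASS_II
    if pm2 in ("D", "E"):
        return CLASS_III
    return CLASS_NONE


def extract_cterm_peptides(
    proteome: list[ProteinRecord],
    sites: list[PhosphositeAnnotation],
    config: DesignConfig = DesignConfig(),
) -> list[CTermPeptide]:
    """Collect unique phosphosite-bearing C-terminal L-mers from a proteome.

    A protein contributes iff at least one validated S/T site falls in its
    last L residues.  Annotations whose residue disagrees with the protein
    sequence are rejected with a log message.  Identical C-terminal L-mers
    from different proteins are merged: site sets unioned, all protein ids
    kept.  Proteins shorter than L, or with ambiguous residues in the last
    L, are skipped.
    """
    by_protein: dict[str, ProteinRecord] = {p.protein_id: p for p in proteome}
    # aa_seq -> (site set, protein ids, p-index -> kinase set)
    merged: dict[str, tuple[set[int], set[str], dict[int, set[str]]]] = {}

    for ann in sites:
        prot = by_protein.get(ann.protein_id)
        if prot is None:
            logger.warning("annotation %s:%d: unknown protein, rejected", ann.protein_id, ann.position)
            continue
        n = len(prot.sequence)
        if not 1 <= ann.position <= n:
            logger.warning("annotation %s:%d: position outside protein (len %d), rejected",
                           ann.protein_id, ann.position, n)
            continue
        if prot.sequence[ann.position - 1] != ann.residue:
            logger.warning("annotation %s:%d: residue mismatch (%s != %s), rejected",
                           ann.protein_id, ann.position,
                           prot.sequence[ann.position - 1], ann.residue)
            continue
        if n < config.L:
            logger.warning("protein %s shorter than L=%d, skipped", prot.protein_id, config.L)
            continue
        p = ann.position - n
        if p < -(config.L - 1):
            continue  # site upstream of the displayed window
        cterm = prot.sequence[-config.L :]
        if set(cterm) - set("ACDEFGHIKLMNPQRSTVWY"):
            logger.warning("protein %s: ambiguous residue in C-terminal %d-mer, skipped",
                           prot.protein_id, config.L)
            continue
        sites_set, ids, kin = merged.setdefault(cterm, (set(), set(), {}))
        sites_set.add(p)
        ids.add(prot.protein_id)
        if ann.kinase:
            kin.setdefault(p, set()).add(ann.kinase)

    peptides = [
        CTermPeptide(
            aa_seq=aa,
            site_positions=frozenset(site_set),
            source_proteins=frozenset(ids),
            kinases=tuple(sorted((p, tuple(sorted(ks))) for p, ks in kin.items())),
        )
        for aa, (site_set, ids, kin) in sorted(merged.items())
    ]
    if not peptides:
        raise DesignError("no designable peptides")
    return peptides


def _apply_mask(aa_seq: str, mask: frozenset[int], mimetic_residue: str = "E") -> str:
    L = len(aa_seq)
    chars = list(aa_seq)
    for p in mask:
        chars[L - 1 + p] = mimetic_residue
    return "".join(chars)


def enumerate_variants(
    peptide: CTermPeptide, config: DesignConfig = DesignConfig()
) -> list[LibraryEntry]:
    """Expand a peptide into its 2^k wild-type + phosphomimetic variants.

    One entry per subset of ``site_positions`` (the empty subset is the
    wild type), with deterministic ids.  Entries carry amino-acid variants
    only; nucleotide sequences are filled in by :func:`build_design` or
    :func:`assemble_oligo`.
    """
    k = len(peptide.site_positions)
    if k < 1:
        raise DesignError(f"peptide {peptide.peptide_id} has no phosphosites")
    if k > config.max_sites:
        raise DesignError(
            f"peptide {peptide.peptide_id} has {k} sites, above cap {config.max_sites}"
        )
    sites = sorted(peptide.site_positions)
    entries = []
    for r in range(k + 1):
        for combo in itertools.combinations(sites, r):
            mask = frozenset(combo)
            entries.append(
                LibraryEntry(
                    entry_id=f"{peptide.peptide_id}:{mask_to_str(mask)}",
                    peptide=peptide,
                    mimetic_mask=mask,
                    aa_seq=_apply_mask(peptide.aa_seq, mask, config.mimetic_residue),
                )
            )
    return entries


def _find_forbidden(oligo: str, insert_start: int, insert_end: int,
                    motifs: tuple[str, ...]) -> int | None:
    """Leftmost start of a forbidden motif overlapping the insert, else None."""
    hits = []
    for motif in motifs:
        start = 0
        while (i := oligo.find(motif, start)) != -1:
            if i < insert_end and i + len(motif) > insert_start:
                hits.append(i)
            start = i + 1
    return min(hits) if hits else None


def assemble_oligo(entry: LibraryEntry, config: DesignConfig = DesignConfig()) -> LibraryEntry:
    """Attach flanks and recode away forbidden restriction-site motifs.

    The oligo is ``flank5 + nt_seq + flank3``.  Any forbidden motif
    occurring within the insert or across an insert/flank junction is
    removed by swapping the leftmost overlapping codon for its next-ranked
    synonym (then the next codon once a family is exhausted), preserving
    the amino-acid sequence.  Raises :class:`DesignError` if no synonymous
    recoding removes the motif.
    """
    nt = entry.nt_seq or reverse_translate(entry.aa_seq, config.codon_table)
    ins_start, ins_len = len(config.flank5), len(nt)
    rank_state = [0] * (ins_len // 3)  # current synonym rank per codon

    for _ in range(10 * len(rank_state) + 10):
        oligo = config.flank5 + nt + config.flank3
        hit = _find_forbidden(oligo, ins_start, ins_start + ins_len, config.forbidden_sites)
        if hit is None:
            return replace(entry, nt_seq=nt, oligo=oligo)
        # codons of the insert overlapping the motif, leftmost first
        motif_len = max(len(m) for m in config.forbidden_sites)
        lo = max(hit - ins_start, 0) // 3
        hi = min((hit + motif_len - 1 - ins_start) // 3, len(rank_state) - 1)
        for ci in range(lo, hi + 1):
            aa = entry.aa_seq[ci]
            if rank_state[ci] + 1 < len(RANKED_CODONS[aa]):
                rank_state[ci] += 1
                new_codon = RANKED_CODONS[aa][rank_state[ci]]
                logger.info("recoding %s codon %d -> %s to remove forbidden site",
                            entry.entry_id, ci, new_codon)
                nt = nt[: 3 * ci] + new_codon + nt[3 * ci + 3 :]
                break
        else:
            break
    raise DesignError(f"forbidden motif unavoidable in entry {entry.entry_id}")


def build_design(
    proteome: list[ProteinRecord],
    sites: list[PhosphositeAnnotation],
    config: DesignConfig = DesignConfig(),
) -> list[LibraryEntry]:
    """Full design: peptides → variants → codon-optimized oligos."""
    entries = []
    for pep in extract_cterm_peptides(proteome, sites, config):
        for e in enumerate_variants(pep, config):
            entries.append(assemble_oligo(e, config))
    return entries


def design_statistics(entries: list[LibraryEntry],
                      phi_set: frozenset[str] = DEFAULT_PHI) -> dict:
    """Design summary: counts, PDZbm class fractions, class I site positions.

    Class fractions are over wild-type peptides; the p-index distribution
    is over all phosphosites of class I wild-type peptides (so the share
    at p-2 is directly comparable across designs).
    """
    wt = [e for e in entries if e.is_wild_type]
    classes = {e.entry_id: classify_pdzbm(e.aa_seq, phi_set) for e in wt}
    n_wt = len(wt)
    frac = {
        cls: 100.0 * sum(v == cls for v in classes.values()) / n_wt if n_wt else 0.0
        for cls in (CLASS_I, CLASS_II, CLASS_III, CLASS_NONE)
    }
    class1_sites = [
        p for e in wt if classes[e.entry_id] == CLASS_I for p in e.peptide.site_positions
    ]
    pos_dist = {
        p: 100.0 * class1_sites.count(p) / len(class1_sites)
        for p in sorted(set(class1_sites))
    } if class1_sites else {}
    return {
        "n_peptides": n_wt,
        "n_entries": len(entries),
        "n_mimetic": len(entries) - n_wt,
        "class_fractions_pct": frac,
        "classI_site_p_distribution_pct": pos_dist,
    }


# ---------------------------------------------------------------- serialization

DESIGN_COLUMNS = [
    "entry_id", "peptide_id", "source_proteins", "aa_seq", "mimetic_mask",
    "site_positions", "pdzbm_class", "nt_seq", "oligo", "kinases",
]


def _kinases_to_str(kin: tuple[tuple[int, tuple[str, ...]], ...]) -> str:
    return ";".join(f"{p}:{','.join(ks)}" for p, ks in kin)


def _kinases_from_str(s: str) -> tuple[tuple[int, tuple[str, ...]], ...]:
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        p, ks = part.split(":", 1)
        out.append((int(p), tuple(ks.split(","))))
    return tuple(out)


def design_frame(entries: list[LibraryEntry],
                 phi_set: frozenset[str] = DEFAULT_PHI) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append({
            "entry_id": e.entry_id,
            "peptide_id": e.peptide.peptide_id,
            "source_proteins": ",".join(sorted(e.peptide.source_proteins)),
            "aa_seq": e.aa_seq,
            "mimetic_mask": mask_to_str(e.mimetic_mask),
            "site_positions": ",".join(str(p) for p in sorted(e.peptide.site_positions)),
            "pdzbm_class": classify_pdzbm(e.aa_seq, phi_set),
            "nt_seq": e.nt_seq,
            "oligo": e.oligo,
            "kinases": _kinases_to_str(e.peptide.kinases),
        })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def write_design(entries: list[LibraryEntry], tsv_path: str | Path,
                 fasta_path: str | Path | None = None,
                 phi_set: frozenset[str] = DEFAULT_PHI) -> None:
    """Serialize a design as TSV (one row per entry) plus an oligo FASTA."""
    df = design_frame(entries, phi_set)
    df.to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for e in entries:
                fh.write(f">{e.entry_id}\n{e.oligo}\n")


def read_design(tsv_path: str | Path) -> list[LibraryEntry]:
    """Inverse of :func:`write_design` (lossless round-trip)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    peptides: dict[str, CTermPeptide] = {}
    entries = []
    for row in df.itertuples(index=False):
        pid = row.peptide_id
        if pid not in peptides:
            sites = frozenset(int(x) for x in row.site_positions.split(",") if x)
            peptides[pid] = CTermPeptide(
                aa_seq=pid,
                site_positions=sites,
                source_proteins=frozenset(row.source_proteins.split(",")),
                kinases=_kinases_from_str(row.kinases),
            )
        mask = (frozenset() if row.mimetic_mask == "wt"
                else frozenset(int(x) for x in row.mimetic_mask.split(",")))
        entries.append(LibraryEntry(
            entry_id=row.entry_id, peptide=peptides[pid], mimetic_mask=mask,
            aa_seq=row.aa_seq, nt_seq=row.nt_seq, oligo=row.oligo,
        ))
    return entries


def read_proteome_fasta(path: str | Path) -> list[ProteinRecord]:
    from Bio import SeqIO

    return [
        ProteinRecord(protein_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_phosphosites_tsv(path: str | Path) -> list[PhosphositeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        PhosphositeAnnotation(
            protein_id=r.protein_id,
            position=int(r.position),
            residue=r.residue,
            source=getattr(r, "source", "known") or "known",
            kinase=getattr(r, "kinase", "") or None,
        )
        for r in df.itertuples(index=False)
    ]


def verify_design(entries: list[LibraryEntry], config: DesignConfig = DesignConfig()) -> None:
    """Internal consistency checks; raises :class:`DesignError` on violation."""
    for e in entries:
        if e.nt_seq and translate(e.nt_seq) != e.aa_seq:
            raise DesignError(f"{e.entry_id}: nt_seq does not translate to aa_seq")
        expected = _apply_mask(e.peptide.aa_seq, e.mimetic_mask, config.mimetic_residue)
        if e.aa_seq != expected:
            raise DesignError(f"{e.entry_id}: aa_seq inconsistent with mimetic mask")
        if e.oligo:
            ins = len(config.flank5)
            if _find_forbidden(e.oligo, ins, ins + len(e.nt_seq), config.forbidden_sites) is not None:
                raise DesignError(f"{e.entry_id}: forbidden motif present in oligo")
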