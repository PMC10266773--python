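"""KIR/HLA genotype scoring: ligand motifs, functional iKIR counts,
and per-cell functional/nonfunctional classification.

An inhibitory KIR (iKIR) is "functional" in an individual only when the
genome also carries an HLA class I allele encoding its ligand motif:
KIR2DL1 binds C2-group HLA-C, KIR2DL2 binds C1 (and, more weakly, C2),
KIR2DL3 binds C1, and KIR3DL1 binds Bw4 (including the Bw4-motif HLA-A
alleles A*23/A*24/A*32).  The per-individual count of such iKIR-ligand
gene pairs ranges 0-4.  KIR3DL2 is a framework gene with distinct
biology; its classical ligands (A*03/A*11, and B*27 homodimers) are
handled only as an exclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Genotype",
    "LigandMotifs",
    "IkirScore",
    "UnknownAlleleError",
    "parse_allele",
    "hla_motifs",
    "count_functional_ikir",
    "classify_cell",
    "kir3dl2_filter",
    "DEFAULT_MOTIF_TABLE",
]

IKIR_GENES = ("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1", "KIR3DL2")
SCORED_GENES = ("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1")

# gene -> motifs that make it functional
LIGAND_RULES: dict[str, tuple[str, ...]] = {
    "KIR2DL1": ("C2",),
    "KIR2DL2": ("C1", "C2"),
    "KIR2DL3": ("C1",),
    "KIR3DL1": ("Bw4",),
}


class UnknownAlleleError(KeyError):
    """Raised when an HLA allele is absent from the motif table.

    Silent defaults would mis-count functional pairs, so unknown alleles
    are a loud error; extend the table with user rows instead.
    """


# Minimal built-in motif table.  Keys are allele-group prefixes
# (locus*group) or full 2-field alleles; 2-field entries take priority.
# HLA-C groups follow the position-80 dimorphism (Asn -> C1, Lys -> C2);
# HLA-B alleles are Bw4 or Bw6, with B*46/B*73 additionally carrying the
# C1 epitope; A*23/A*24/A*32 carry Bw4.  Extend via the ``motif_table``
# argument for alleles outside this list.
DEFAULT_MOTIF_TABLE: dict[str, tuple[str, ...]] = {
    # HLA-C C1 groups
    **{g: ("C1",) for g in
       ("C*01", "C*03", "C*07", "C*08", "C*12", "C*14", "C*16")},
    # HLA-C C2 groups
    **{g: ("C2",) for g in
       ("C*02", "C*04", "C*05", "C*06", "C*15", "C*17", "C*18")},
    # HLA-B Bw4 groups
    **{g: ("Bw4",) for g in
       ("B*13", "B*27", "B*37", "B*38", "B*44", "B*49", "B*51", "B*52",
        "B*53", "B*57", "B*58", "B*59", "B*77")},
    # HLA-B Bw6 groups (no KIR ligand among the scored genes)
    **{g: ("Bw6",) for g in
       ("B*07", "B*08", "B*14", "B*18", "B*35", "B*39", "B*40", "B*41",
        "B*42", "B*45", "B*48", "B*50", "B*54", "B*55", "B*56", "B*60",
        "B*61", "B*62", "B*71", "B*72", "B*78", "B*81")},
    # B*15 is mostly Bw6; Bw4 members are listed allele-level
    "B*15": ("Bw6",),
    "B*15:13": ("Bw4",),
    "B*15:16": ("Bw4",),
    "B*15:17": ("Bw4",),
    "B*15:23": ("Bw4",),
    "B*15:24": ("Bw4",),
    # public-epitope exceptions: Bw6 alleles carrying the C1 epitope
    "B*46": ("Bw6", "C1"),
    "B*73": ("Bw6", "C1"),
    # HLA-A: Bw4-motif alleles; all others carry no scored-KIR ligand
    "A*23": ("Bw4",),
    "A*24": ("Bw4",),
    "A*32": ("Bw4",),
    **{g: () for g in
       ("A*01", "A*02", "A*03", "A*11", "A*25", "A*26", "A*29", "A*30",
        "A*31", "A*33", "A*34", "A*36", "A*66", "A*68", "A*69", "A*74",
        "A*80")},
}

# KIR3DL2 classical ligands used by the exclusion filter
_A3_A11_GROUPS = ("A*03", "A*11")
_B27_GROUP = "B*27"


def parse_allele(name: str) -> str:
    """Normalise an HLA allele name to 2-field resolution.

    Accepts an optional ``HLA-`` prefix and 2-4 field names; extra
    fields are truncated (``HLA-B*57:01:01`` -> ``B*57:01``).
    """
    s = name.strip().upper()
    if s.startswith("HLA-"):
        s = s[4:]
    if "*" not in s:
        raise ValueError(f"malformed HLA allele name: {name!r}")
    locus, rest = s.split("*", 1)
    fields = rest.split(":")
    if locus not in ("A", "B", "C") or not fields[0]:
        raise ValueError(f"malformed HLA allele name: {name!r}")
    return f"{locus}*{':'.join(fields[:2])}"


def _lookup(allele: str, table: Mapping[str, tuple[str, ...]]
            ) -> tuple[str, ...]:
    norm = parse_allele(allele)
    if norm in table:
        return tuple(table[norm])
    group = norm.split(":")[0]
    if group in table:
        return tuple(table[group])
    raise UnknownAlleleError(
        f"allele {allele!r} (normalised {norm!r}) not in the motif table; "
        "supply a motif_table entry for it")


@dataclass(frozen=True)
class LigandMotifs:
    """Ligand motifs encoded by an HLA allele list."""

    has_C1: bool = False
    has_C2: bool = False
    has_Bw4: bool = False
    has_A3_A11: bool = False
    has_B27: bool = False

    def has(self, motif: str) -> bool:
        return getattr(self, f"has_{motif}")


@dataclass(frozen=True)
class IkirScore:
    functional_count: int
    inhibitory_score: float
    raw_ikir_count: int

    def __post_init__(self):
        if not 0 <= self.functional_count <= 4:
            raise ValueError("functional_count must be 0-4")
        if self.functional_count > self.raw_ikir_count:
            raise ValueError("functional_count cannot exceed raw_ikir_count")


@dataclass(frozen=True)
class Genotype:
    """KIR gene presence plus HLA-A/B/C allele list for one individual."""

    individual_id: str
    kir_present: frozenset = frozenset()
    hla_alleles: tuple = ()

    def __post_init__(self):
        unknown = set(self.kir_present) - set(IKIR_GENES)
        if unknown:
            raise ValueError(f"unknown KIR genes: {sorted(unknown)}")

    @staticmethod
    def make(individual_id: str, kir: Iterable[str], hla: Iterable[str]
             ) -> "Genotype":
        return Genotype(individual_id, frozenset(kir), tuple(hla))


def hla_motifs(hla_alleles: Iterable[str],
               motif_table: Mapping[str, tuple[str, ...]] | None = None
               ) -> LigandMotifs:
    """Derive the ligand motifs encoded by an HLA allele list."""
    alleles = list(hla_alleles)
    if not alleles:
        raise ValueError("allele list is empty")
    table = dict(DEFAULT_MOTIF_TABLE)
    if motif_table:
        table.update({parse_allele(k) if ":" in k else k: tuple(v)
                      for k, v in motif_table.items()})
    motifs: set[str] = set()
    a3a11 = b27 = False
    for allele in alleles:
        norm = parse_allele(allele)
        motifs.update(_lookup(allele, table))
        group = norm.split(":")[0]
        if group in _A3_A11_GROUPS:
            a3a11 = True
        if group == _B27_GROUP:
            b27 = True
    return LigandMotifs(
        has_C1="C1" in motifs,
        has_C2="C2" in motifs,
        has_Bw4="Bw4" in motifs,
        has_A3_A11=a3a11,
        has_B27=b27,
    )


def count_functional_ikir(genotype: Genotype,
                          weights: Mapping[str, float] | None = None,
                          motif_table: Mapping[str, tuple[str, ...]] | None = None
                          ) -> IkirScore:
    """Count iKIR-ligand gene pairs (0-4) and the weighted inhibitory score.

    A gene among KIR2DL1/2DL2/2DL3/3DL1 contributes one unit when
    present together with at least one allele encoding a ligand motif it
    binds.  ``weights`` (default 1.0 per pair) scale each pair's
    contribution to the inhibitory score; ``raw_ikir_count`` ignores
    ligands entirely.
    """
    motifs = hla_motifs(genotype.hla_alleles, motif_table)
    count = 0
    score = 0.0
    raw = 0
    for gene in SCORED_GENES:
        if gene not in genotype.kir_present:
            continue
        raw += 1
        if any(motifs.has(m) for m in LIGAND_RULES[gene]):
            count += 1
            score += (weights or {}).get(gene, 1.0)
    return IkirScore(functional_count=count, inhibitory_score=score,
                     raw_ikir_count=raw)


# expression is measured with antibody granularity: 2DL2 and 2DL3 are
# indistinguishable and reported as the composite channel "KIR2DL2/L3"
EXPRESSION_CHANNELS = ("KIR2DL1", "KIR2DL2/L3", "KIR3DL1")


def classify_cell(expressed_ikirs: Iterable[str], genotype: Genotype,
                  motif_table: Mapping[str, tuple[str, ...]] | None = None
                  ) -> str:
    """Classify a cell's iKIR expression as functional / nonfunctional /
    negative / ambiguous.

    A cell is *functional* if any expressed iKIR has its ligand encoded
    in the genome (a functional signal is assumed dominant),
    *nonfunctional* if it expresses iKIRs but none has a ligand,
    *negative* if it expresses none.  The *ambiguous* case arises for
    KIR2DL2/L3-positive cells in individuals who carry both genes with
    KIR2DL2 functional (C2 only) but KIR2DL3 not: the antibody cannot
    resolve which gene product is expressed.
    """
    expressed = set(expressed_ikirs)
    unknown = expressed - set(EXPRESSION_CHANNELS)
    if unknown:
        raise ValueError(f"unknown expression channels: {sorted(unknown)}")
    if not expressed:
        return "negative"
    motifs = hla_motifs(genotype.hla_alleles, motif_table)
    kir = genotype.kir_present

    def gene_functional(gene: str) -> bool:
        return any(motifs.has(m) for m in LIGAND_RULES[gene])

    statuses: list[str] = []
    for channel in expressed:
        if channel == "KIR2DL2/L3":
            genes = [g for g in ("KIR2DL2", "KIR2DL3") if g in kir]
            if not genes:
                # expression without the gene is inconsistent input
                raise ValueError(
                    "cell expresses KIR2DL2/L3 but genotype carries neither gene")
            flags = {g: gene_functional(g) for g in genes}
            if all(flags.values()):
                statuses.append("functional")
            elif not any(flags.values()):
                statuses.append("nonfunctional")
            else:
                # only KIR2DL2 functional, KIR2DL3 not: unresolvable
                statuses.append("ambiguous")
        else:
            if channel not in kir:
                raise ValueError(
                    f"cell expresses {channel} but genotype lacks the gene")
            statuses.append("functional" if gene_functional(channel)
                            else "nonfunctional")
    if "functional" in statuses:
        return "functional"
    if "ambiguous" in statuses:
        return "ambiguous"
    return "nonfunctional"


def kir3dl2_filter(genotype: Genotype, mode: str = "primary") -> bool:
    """Decide whether an individual enters the lifespan analysis.

    ``primary`` excludes carriers of any KIR3DL2 ligand: the classical
    A*03/A*11, and B*27 (whose heavy-chain homodimers bind KIR3DL2
    exceptionally strongly).  ``sensitivity`` re-admits the A*03/A*11
    carriers (their KIR3DL2-negative cells classify by the standard
    rules) but still excludes B*27 carriers.  Returns True when the
    individual is included.
    """
    if mode not in ("primary", "sensitivity"):
        raise ValueError("mode must be 'primary' or 'sensitivity'")
    motifs = hla_motifs(genotype.hla_alleles)
    if mode == "sensitivity":
        return not motifs.has_B27
    return not (motifs.has_A3_A11 or motifs.has_B27)
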