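"""Bisulfite PCR marker panel: assay geometry and in-silico PCR.

A panel is a set of singleplex bisulfite PCR assays, one per target CpG.
Each assay carries its primer pair (designed against bisulfite-converted
DNA, never overlapping a CpG), the converted-space amplicon reference, the
0-based offsets of every CpG cytosine in the amplicon (target plus
adjacent, all quantified) and the offsets of non-CpG cytosines that act as
bisulfite conversion controls.

Reference convention: ``reference_seq`` is the amplicon in
fully-methylated, fully-converted top form — CpG cytosines appear as C,
every non-CpG cytosine as T. ``control_offsets`` therefore point at
positions that read T in a converted molecule and C only on conversion
failure; ``cpg_offsets`` read C when methylated and T when unmethylated.

``in_silico_bisulfite_pcr`` validates assays against genomic sequence: it
converts both strands (non-CpG C→T, CpG C left ambiguous as Y matching C
or T, so the methylation state can never change primer binding), finds the
primer sites and returns the unique product.

The packaged 16-marker default panel ships the published primer pairs,
amplicon lengths and GRCh37 target coordinates; its amplicon reference
sequences are SYNTHETIC genomic regions constructed to honour those
primers and lengths (the true amplicon sequences are not distributed), and
are derived at load time by running the in-silico PCR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

__all__ = [
    "CpGMarker",
    "Amplicon",
    "MarkerPanel",
    "PanelError",
    "MultipleProductsError",
    "PCRProduct",
    "load_panel",
    "save_panel",
    "in_silico_bisulfite_pcr",
    "bisulfite_convert",
    "default_panel",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTYN", "TGCARN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    pass


class MultipleProductsError(PanelError):
    pass


@dataclass(frozen=True)
class CpGMarker:
    cpg_id: str
    chrom: str
    position: int  # 1-based GRCh37 coordinate of the CpG cytosine
    gene: str = ""
    annotation: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise PanelError(f"{self.cpg_id}: genomic position must be >= 1")


@dataclass(frozen=True)
class Amplicon:
    cpg_id: str
    fwd_primer: str
    rev_primer: str
    template_strand: str  # "top-converted" | "bottom-converted"
    reference_seq: str
    cpg_offsets: tuple[int, ...]
    control_offsets: tuple[int, ...]
    target_offset: int  # offset of the assay's named CpG
    anneal_temp: float = 50.0

    @property
    def length(self) -> int:
        return len(self.reference_seq)

    def matching_reference(self) -> str:
        """Reference with Y at every variable (CpG or control) position."""
        chars = list(self.reference_seq)
        for off in self.cpg_offsets + self.control_offsets:
            chars[off] = "Y"
        return "".join(chars)

    def validate(self) -> None:
        for name, primer in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if "CG" in primer.upper():
                raise PanelError(
                    f"{self.cpg_id}: {name} primer contains a CpG dinucleotide"
                )
        offsets = self.cpg_offsets + self.control_offsets
        if len(set(self.cpg_offsets) & set(self.control_offsets)):
            raise PanelError(f"{self.cpg_id}: CpG and control offsets overlap")
        for off in offsets:
            if not 0 <= off < self.length:
                raise PanelError(f"{self.cpg_id}: offset {off} outside amplicon")
        if not 0 <= self.target_offset < self.length:
            raise PanelError(f"{self.cpg_id}: target offset outside amplicon")
        if self.target_offset not in self.cpg_offsets:
            raise PanelError(f"{self.cpg_id}: target offset not among CpG offsets")
        for off in self.cpg_offsets:
            if self.reference_seq[off] != "C":
                raise PanelError(f"{self.cpg_id}: CpG offset {off} is not a C")


@dataclass
class MarkerPanel:
    markers: dict[str, CpGMarker] = field(default_factory=dict)
    amplicons: dict[str, Amplicon] = field(default_factory=dict)

    def __len__(self):
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons.values())

    def add(self, marker: CpGMarker, amplicon: Amplicon) -> None:
        if marker.cpg_id in self.markers:
            raise PanelError(f"duplicate marker id {marker.cpg_id}")
        amplicon.validate()
        self.markers[marker.cpg_id] = marker
        self.amplicons[marker.cpg_id] = amplicon

    def validate(self) -> None:
        if not self.amplicons:
            raise PanelError("panel is empty")
        for amp in self.amplicons.values():
            amp.validate()

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cpg_id, amp in self.amplicons.items():
                fh.write(f">{cpg_id}\n{amp.reference_seq}\n")


@dataclass(frozen=True)
class PCRProduct:
    length: int
    template_strand: str
    reference_seq: str
    cpg_offsets: tuple[int, ...]
    control_offsets: tuple[int, ...]
    start: int  # product start within the converted template


def bisulfite_convert(seq: str) -> str:
    """Top-strand bisulfite conversion: non-CpG C→T, CpG C→Y (C or T)."""
    seq = seq.upper()
    out = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C":
            out.append("Y" if i + 1 < n and seq[i + 1] == "G" else "T")
        else:
            out.append(base)
    return "".join(out)


def _find_primer(template: str, primer: str) -> list[int]:
    """Start offsets where the primer matches (template Y matches C or T)."""
    hits = []
    for i in range(len(template) - len(primer) + 1):
        window = template[i : i + len(primer)]
        ok = all(
            t == p or (t == "Y" and p in "CT")
            for t, p in zip(window, primer.upper())
        )
        if ok:
            hits.append(i)
    return hits


def in_silico_bisulfite_pcr(
    genomic_seq: str, fwd_primer: str, rev_primer: str
) -> PCRProduct | None:
    """Predict the bisulfite PCR product from genomic sequence.

    Both converted templates (top and bottom strand) are searched for the
    forward primer and, downstream of it, the reverse complement of the
    reverse primer; product length is inclusive of both primers. Returns
    the unique product, ``None`` when no primer pair sites exist, and
    raises :class:`MultipleProductsError` on ambiguous multi-site hits.
    """
    genomic_seq = genomic_seq.upper()
    products = []
    for strand, source in (
        ("top-converted", genomic_seq),
        ("bottom-converted", reverse_complement(genomic_seq)),
    ):
        template = bisulfite_convert(source)
        rc_rev = reverse_complement(rev_primer.upper())
        # primer-space rc of rev contains A/G where template has A/G; its
        # C/T positions must tolerate Y the same way
        fwd_hits = _find_primer(template, fwd_primer)
        rev_hits = _find_primer(template, rc_rev)
        for i in fwd_hits:
            for j in rev_hits:
                end = j + len(rc_rev)
                if end > i + len(fwd_primer) and j >= i:
                    product_tpl = template[i:end]
                    ref = product_tpl.replace("Y", "C")
                    cpg_offsets = tuple(
                        k for k, b in enumerate(product_tpl) if b == "Y"
                    )
                    control_offsets = tuple(
                        k
                        for k, b in enumerate(source[i:end])
                        if b == "C" and product_tpl[k] == "T"
                    )
                    products.append(
                        PCRProduct(end - i, strand, ref, cpg_offsets,
                                   control_offsets, i)
                    )
    if not products:
        return None
    if len(products) > 1:
        raise MultipleProductsError(
            f"{len(products)} candidate products (lengths "
            f"{[p.length for p in products]})"
        )
    return products[0]


# ---------------------------------------------------------------------------
# Panel serialization
# ---------------------------------------------------------------------------


def save_panel(panel: MarkerPanel, path) -> None:
    payload = []
    for cpg_id, amp in panel.amplicons.items():
        record = asdict(panel.markers[cpg_id])
        record.update(asdict(amp))
        record.pop("cpg_id")
        record["cpg_id"] = cpg_id
        payload.append(record)
    with open(path, "w") as fh:
        json.dump({"markers": payload}, fh, indent=1)


def load_panel(path) -> MarkerPanel:
    """Load a full panel JSON (markers + amplicon geometry); validates all
    invariants and reports violations with the offending marker id."""
    with open(path) as fh:
        payload = json.load(fh)
    records = payload.get("markers", [])
    if not records:
        raise PanelError(f"{path}: empty panel")
    panel = MarkerPanel()
    for rec in records:
        marker = CpGMarker(
            rec["cpg_id"], rec["chrom"], rec["position"],
            rec.get("gene", ""), rec.get("annotation", ""),
        )
        amp = Amplicon(
            cpg_id=rec["cpg_id"],
            fwd_primer=rec["fwd_primer"],
            rev_primer=rec["rev_primer"],
            template_strand=rec.get("template_strand", "top-converted"),
            reference_seq=rec["reference_seq"],
            cpg_offsets=tuple(rec["cpg_offsets"]),
            control_offsets=tuple(rec["control_offsets"]),
            target_offset=rec["target_offset"],
            anneal_temp=rec.get("anneal_temp", 50.0),
        )
        panel.add(marker, amp)
    return panel


# ---------------------------------------------------------------------------
# Default 16-marker panel with synthetic reference regions
# ---------------------------------------------------------------------------


def _synthetic_genomic_region(
    fwd: str, rev: str, length: int, seed: int, n_cpg: int = 4, n_ctrl: int = 8,
    flank: int = 60,
):
    """Construct a synthetic genomic region whose bisulfite PCR product with
    the given primers has exactly the requested length.

    The amplicon interior receives ``n_cpg`` CpG dinucleotides and
    ``n_ctrl`` non-CpG cytosines (conversion controls); primer regions stay
    CpG-free as designed. Returns (region, target CpG offset in amplicon).
    """
    rng = np.random.default_rng(seed)
    rc_rev = reverse_complement(rev.upper())
    mid_len = length - len(fwd) - len(rc_rev)
    if mid_len < n_cpg * 3 + n_ctrl + 4:
        n_cpg = max(2, mid_len // 8)
        n_ctrl = max(3, mid_len // 8)
    mid = list(rng.choice(list("ATG"), size=mid_len))
    # CpG placements: need slots i, i+1 spaced by >= 3, away from the edges
    slots = []
    attempt = 0
    while len(slots) < n_cpg and attempt < 500:
        attempt += 1
        i = int(rng.integers(2, mid_len - 3))
        if all(abs(i - s) >= 4 for s in slots):
            slots.append(i)
    slots.sort()
    for i in slots:
        mid[i], mid[i + 1] = "C", "G"
    taken = set()
    for i in slots:
        taken.update((i - 1, i, i + 1))
    controls = []
    attempt = 0
    while len(controls) < n_ctrl and attempt < 1000:
        attempt += 1
        q = int(rng.integers(1, mid_len - 2))
        if q in taken or (q + 1) in taken or mid[q + 1] == "G" or mid[q - 1] == "C":
            continue
        mid[q] = "C"
        taken.update((q, q + 1))
        controls.append(q)
    # target CpG: the placed CpG nearest the amplicon centre
    centre = mid_len / 2
    target_mid = min(slots, key=lambda i: abs(i - centre))
    target_offset = len(fwd) + target_mid
    left = "".join(rng.choice(list("ATG"), size=flank))
    right = "".join(rng.choice(list("ATG"), size=flank))
    region = left + fwd.upper() + "".join(mid) + rc_rev + right
    return region, target_offset


# Published assay table: primer pairs, amplicon lengths (bp), annealing
# temperatures and GRCh37 target coordinates for the 16-CpG aging signature.
PANEL_ASSAYS = [
    ("cg19761273", "CSNK1D", "17", 80232096, "TGTTTAGTTTGAAGATTGAG", "CCTTATTTCCTTTACAAAAA", 150, 50),
    ("cg27544190", "C21orf63", "21", 33785434, "GGGTAGGATTAAAGTTGA", "CTTAAAAATAACAATCCCC", 106, 50),
    ("cg03286783", "CASC4", "15", 44580973, "GTTTTAGTTAGTGGGTG", "CCCCTCCTCAAATCAAA", 181, 52),
    ("cg01511567", "SSRP1", "11", 57103631, "TATTAGATTTAGTATAGGGG", "CCCACAACTATTCAAATA", 132, 50),
    ("cg07158339", "FXN", "9", 71650237, "GGAATATGTTTTGTTTAAAA", "TAATTAACCTCTCTATACCT", 122, 48),
    ("cg05442902", "P2RXL1", "22", 21369010, "GTATGTTTTGGTTTTTGT", "AATAACCTCTAAACTAACC", 109, 52),
    ("cg24450312", "RASSF5", "1", 206681158, "GTTATTTATAGAGTTTGAG", "TCTACTACAAACCAAA", 201, 50),
    ("cg17274064", "ERG", "21", 40033892, "AGGGAATAAGTATTTTTT", "CTCACAATCAAACTTCTATATAC", 139, 48),
    ("cg02085507", "TRIP10", "19", 6739192, "GTTAATGGATTTGGTTTTG", "AACTCAAAAAATCCTTCCT", 186, 48),
    ("cg20692569", "FZD9", "7", 72848481, "TTGTTGTTGTGGTAGT", "AACCCAACAAATTAAA", 160, 48),
    ("cg04528819", "KLF14", "7", 130418315, "AATAGGTTTTGGTGTAGTT", "CAACCTCTAATAAATTCTCT", 138, 50),
    ("cg08370996", "NR2F2", "15", 96874031, "GTGTTAAAGTTTATTATATAGA", "AAAAAAAAAAACACACAC", 187, 52),
    ("cg04084157", "VGF", "7", 100809049, "GAGGGTGTTTGTTTTTTT", "AACATTTCATTCATTCATTC", 111, 52),
    ("cg22736354", "NHLRC1", "6", 18122719, "GTTGAGTTTAGGAGTTTTAT", "CTTTAAAAAATTTAACCACC", 201, 52),
    ("cg06493994", "SCGN", "6", 25652602, "GGAGAGTAAGTTAAGAAATA", "AACCTACCAAAAACCAAC", 150, 52),
    ("cg02479575", "C19orf30", "19", 4769653, "GGAGGAGAATGTTATTTATT", "CTATCCAAAATTCTAAAAAC", 143, 48),
]


def packaged_panel_path():
    """Path to the shipped 16-marker panel JSON (synthetic references)."""
    return resources.files("epiage").joinpath("data/default_panel_synthetic.json")


def default_panel() -> MarkerPanel:
    """The packaged 16-marker panel with synthetic reference regions.

    Primers, lengths, coordinates and annealing temperatures follow the
    published assay table; the amplicon sequences are synthetic and are
    derived by in-silico bisulfite PCR against constructed genomic regions,
    so loading the default panel exercises the PCR prediction itself.
    """
    panel = MarkerPanel()
    for i, (cpg_id, gene, chrom, pos, fwd, rev, length, tm) in enumerate(PANEL_ASSAYS):
        region, target_offset = _synthetic_genomic_region(fwd, rev, length, seed=1000 + i)
        product = in_silico_bisulfite_pcr(region, fwd, rev)
        if product is None or product.length != length:
            raise PanelError(f"{cpg_id}: synthetic region failed in-silico PCR")
        target = target_offset
        if target not in product.cpg_offsets:
            target = min(product.cpg_offsets, key=lambda o: abs(o - target_offset))
        marker = CpGMarker(cpg_id, chrom, pos, gene, annotation="synthetic reference")
        amp = Amplicon(
            cpg_id=cpg_id,
            fwd_primer=fwd,
            rev_primer=rev,
            template_strand=product.template_strand,
            reference_seq=product.reference_seq,
            cpg_offsets=product.cpg_offsets,
            control_offsets=product.control_offsets,
            target_offset=target,
            anneal_temp=tm,
        )
        panel.add(marker, amp)
    return panel
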