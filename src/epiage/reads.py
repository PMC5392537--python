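"""Paired-end bisulfite amplicon reads: simulation and quantification.

Simulation draws one methylation state per CpG per fragment (Bernoulli at
the true beta), converts unmethylated CpG cytosines and every control
cytosine with the given conversion rate, applies substitution sequencing
errors, and emits both 150-bp mates of each fragment.

Quantification assigns each read to its best-matching amplicon reference
(Y-aware: CpG and control positions match C and T at zero cost), counts
C/T per interrogated offset with overlapping mate bases counted once
(first mate wins), estimates the bisulfite conversion rate from the
control offsets, corrects the raw betas for conversion failure and applies
the minimum-coverage filter (default 1000 reads).

Assignment aligns only unique sequences (counts are restored afterwards):
error-free reads hit an anchored exact matcher, everything else falls back
to semi-global edit-distance alignment with edlib.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import NamedTuple

import edlib
import numpy as np
import pandas as pd

from .panel import Amplicon, MarkerPanel, reverse_complement

__all__ = [
    "ReadRecord",
    "AlignedRead",
    "Assignment",
    "simulate_reads",
    "assign_reads",
    "call_methylation",
    "conversion_rate",
    "correct_conversion",
    "quantify",
    "write_fastq",
    "read_fastq",
    "write_sam",
    "ConversionError",
    "DEFAULT_MIN_READS",
]

DEFAULT_MIN_READS = 1000

_Y_EQUALITIES = [("Y", "C"), ("Y", "T")]


class ConversionError(ValueError):
    pass


class ReadRecord(NamedTuple):
    read_id: str
    mate: int  # 1 or 2
    sequence: str
    quality: str


class AlignedRead(NamedTuple):
    read_id: str
    mate: int
    sequence: str  # oriented to the top (reference) strand
    ref_start: int
    cigar: str | None  # None = exact full-length match
    distance: int


@dataclass
class Assignment:
    by_marker: dict[str, list[AlignedRead]]
    unassigned: list[ReadRecord]

    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_marker.values())


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    panel: MarkerPanel,
    true_betas: dict,
    n_fragments: int = 1000,
    conversion_rate: float = 1.0,
    seq_error_rate: float = 0.0,
    read_len: int = 150,
    seed: int = 0,
    sample_id: str = "sim",
) -> list[ReadRecord]:
    """Simulate paired-end reads for every marker in ``true_betas``.

    ``true_betas`` maps marker id to either a scalar beta (applied to every
    CpG in the amplicon) or a mapping {cpg_offset: beta}. Each fragment's
    CpGs are drawn independently; an unmethylated CpG cytosine and every
    control cytosine convert C→T with probability ``conversion_rate``.
    Substitution errors are applied per mate. Deterministic given ``seed``.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion_rate must lie in [0, 1]")
    if not 0.0 <= seq_error_rate < 1.0:
        raise ValueError("seq_error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[ReadRecord] = []
    for marker_id, beta_spec in true_betas.items():
        if marker_id not in panel.amplicons:
            raise KeyError(f"marker {marker_id} not in panel")
        amp = panel.amplicons[marker_id]
        L = amp.length
        betas = {off: float(beta_spec) for off in amp.cpg_offsets} if np.isscalar(
            beta_spec
        ) else {int(k): float(v) for k, v in beta_spec.items()}
        frag = np.tile(
            np.frombuffer(amp.reference_seq.encode(), dtype="S1"), (n_fragments, 1)
        ).copy()
        for off in amp.cpg_offsets:
            beta = betas.get(off, 0.0)
            methylated = rng.random(n_fragments) < beta
            converted = rng.random(n_fragments) < conversion_rate
            frag[:, off] = np.where(methylated | ~converted, b"C", b"T")
        for off in amp.control_offsets:
            converted = rng.random(n_fragments) < conversion_rate
            frag[:, off] = np.where(converted, b"T", b"C")
        eff_len = min(read_len, L)
        frag8 = frag.view(np.uint8)
        r1 = frag8[:, :eff_len].copy()
        # mate 2 reads the bottom strand from the fragment 3' end
        lut = np.arange(256, dtype=np.uint8)
        for orig, repl in zip(b"ACGT", b"TGCA"):
            lut[orig] = repl
        r2 = lut[frag8][:, ::-1][:, :eff_len].copy()
        base8 = np.frombuffer(b"ACGT", dtype=np.uint8)
        for r in (r1, r2):
            if seq_error_rate > 0:
                err = rng.random(r.shape) < seq_error_rate
                if err.any():
                    r[err] = base8[rng.integers(0, 4, size=int(err.sum()))]
        qual = "I" * eff_len
        for i in range(n_fragments):
            rid = f"{sample_id}:{marker_id}:{i:06d}"
            records.append(ReadRecord(rid, 1, r1[i].tobytes().decode(), qual))
            records.append(ReadRecord(rid, 2, r2[i].tobytes().decode(), qual))
    return records


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def _anchored_matchers(amp: Amplicon, read_len: int):
    """Regexes matching an error-free mate 1 (amplicon prefix) or oriented
    mate 2 (amplicon suffix); CpG/control positions accept C or T."""
    ref = amp.matching_reference()
    eff = min(read_len, amp.length)

    def to_regex(chunk: str) -> re.Pattern:
        return re.compile(
            "".join("[CT]" if b == "Y" else re.escape(b) for b in chunk) + "$"
        )

    return to_regex(ref[:eff]), to_regex(ref[-eff:]), eff


def assign_reads(
    batch: list[ReadRecord],
    panel: MarkerPanel,
    max_divergence: float = 0.1,
    read_len: int = 150,
) -> Assignment:
    """Assign every read to its best-scoring amplicon or the unassigned bin.

    Unique (sequence, mate) pairs are scored once. A read is unassigned
    when its best edit distance exceeds ``max_divergence``·length or when
    two markers tie for best score.
    """
    markers = list(panel.amplicons)
    matchers = {m: _anchored_matchers(panel.amplicons[m], read_len) for m in markers}
    y_refs = {m: panel.amplicons[m].matching_reference() for m in markers}

    cache: dict[tuple[str, int], tuple | None] = {}

    def locate(seq: str, mate: int):
        key = (seq, mate)
        if key in cache:
            return cache[key]
        oriented = seq if mate == 1 else reverse_complement(seq)
        # fast path: anchored exact match against prefix (mate 1) / suffix
        exact = None
        for m in markers:
            pre, suf, eff = matchers[m]
            if len(oriented) != eff:
                continue
            pattern = pre if mate == 1 else suf
            if pattern.fullmatch(oriented):
                if exact is not None:
                    exact = "tie"
                    break
                start = 0 if mate == 1 else panel.amplicons[m].length - eff
                exact = (m, oriented, start, None, 0)
        if exact == "tie":
            result = None
        elif exact is not None:
            result = exact
        else:
            best = second = (None, np.inf)
            for m in markers:
                aln = edlib.align(
                    oriented, y_refs[m], mode="HW", task="distance",
                    additionalEqualities=_Y_EQUALITIES,
                )
                d = aln["editDistance"]
                if d < best[1]:
                    best, second = (m, d), best
                elif d < second[1]:
                    second = (m, d)
            if best[0] is None or best[1] > max_divergence * len(oriented) or (
                second[1] == best[1]
            ):
                result = None
            else:
                aln = edlib.align(
                    oriented, y_refs[best[0]], mode="HW", task="path",
                    additionalEqualities=_Y_EQUALITIES,
                )
                start = aln["locations"][0][0]
                result = (best[0], oriented, start, aln["cigar"], best[1])
        cache[key] = result
        return result

    by_marker: dict[str, list[AlignedRead]] = defaultdict(list)
    unassigned: list[ReadRecord] = []
    for rec in batch:
        hit = locate(rec.sequence, rec.mate)
        if hit is None:
            unassigned.append(rec)
        else:
            m, oriented, start, cigar, dist = hit
            by_marker[m].append(
                AlignedRead(rec.read_id, rec.mate, oriented, start, cigar, dist)
            )
    return Assignment(dict(by_marker), unassigned)


def _offset_base(read: AlignedRead, offset: int) -> str | None:
    """Base the read places at a reference offset, or None if uncovered."""
    if read.cigar is None:
        pos = offset - read.ref_start
        if 0 <= pos < len(read.sequence):
            return read.sequence[pos]
        return None
    ref_pos = read.ref_start
    query_pos = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", read.cigar):
        count = int(count)
        if op in "=XM":
            if ref_pos <= offset < ref_pos + count:
                return read.sequence[query_pos + (offset - ref_pos)]
            ref_pos += count
            query_pos += count
        elif op == "I":
            query_pos += count
        elif op == "D":
            if ref_pos <= offset < ref_pos + count:
                return None  # deleted in the read
            ref_pos += count
    return None


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------


def call_methylation(
    reads: list[AlignedRead],
    amplicon: Amplicon,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Per-offset C/T counts for one amplicon's assigned reads.

    Counts every CpG offset (target plus adjacent) and every control
    offset. Overlapping mate bases count once with mate 1 winning; N and
    other bases go to ``other_count``. ``raw_beta`` is C/(C+T), defined
    only at coverage > 0; ``pass_coverage`` is coverage >= ``min_reads``.
    """
    offsets = sorted(amplicon.cpg_offsets + amplicon.control_offsets)
    kind = {off: "cpg" for off in amplicon.cpg_offsets}
    kind.update({off: "control" for off in amplicon.control_offsets})
    counts = {off: {"C": 0, "T": 0, "other": 0} for off in offsets}

    # group exact full-length matches by (mate, start, length) for
    # vectorised column extraction; gapped alignments take the slow path
    groups: dict[tuple[int, int, int], tuple[list, list]] = defaultdict(
        lambda: ([], [])
    )
    gapped: list[AlignedRead] = []
    for read in reads:
        if read.cigar is None:
            ids, seqs = groups[(read.mate, read.ref_start, len(read.sequence))]
            ids.append(read.read_id)
            seqs.append(read.sequence)
        else:
            gapped.append(read)
    # integer-code read ids once so mate-overlap masks use fast integer isin
    id_codes: dict[str, int] = {}
    arrays = []
    for (mate, start, length), (ids, seqs) in groups.items():
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
            len(seqs), length
        )
        codes = np.fromiter(
            (id_codes.setdefault(i, len(id_codes)) for i in ids),
            dtype=np.int64, count=len(ids),
        )
        arrays.append((mate, start, length, codes, arr))
    gapped_codes = {
        r.read_id: id_codes.setdefault(r.read_id, len(id_codes)) for r in gapped
    }

    C, T = ord("C"), ord("T")
    for off in offsets:
        m1_ids = []
        # mate 1 first (wins mate overlaps)
        for mate, start, length, ids, arr in arrays:
            if mate != 1 or not start <= off < start + length:
                continue
            col = arr[:, off - start]
            counts[off]["C"] += int((col == C).sum())
            counts[off]["T"] += int((col == T).sum())
            counts[off]["other"] += int(((col != C) & (col != T)).sum())
            m1_ids.append(ids)
        for read in gapped:
            if read.mate != 1:
                continue
            base = _offset_base(read, off)
            if base is None:
                continue
            counts[off][base if base in ("C", "T") else "other"] += 1
            m1_ids.append(np.asarray([gapped_codes[read.read_id]], dtype=np.int64))
        m1_concat = (
            np.concatenate(m1_ids) if m1_ids else np.asarray([], dtype=np.int64)
        )
        for mate, start, length, ids, arr in arrays:
            if mate != 2 or not start <= off < start + length:
                continue
            keep = ~np.isin(ids, m1_concat) if len(m1_concat) else np.ones(
                len(ids), dtype=bool
            )
            col = arr[keep, off - start]
            counts[off]["C"] += int((col == C).sum())
            counts[off]["T"] += int((col == T).sum())
            counts[off]["other"] += int(((col != C) & (col != T)).sum())
        m1_set = set(m1_concat.tolist()) if len(m1_concat) else set()
        for read in gapped:
            if read.mate != 2 or gapped_codes.get(read.read_id) in m1_set:
                continue
            base = _offset_base(read, off)
            if base is None:
                continue
            counts[off][base if base in ("C", "T") else "other"] += 1
    rows = []
    for off in offsets:
        c, t, other = counts[off]["C"], counts[off]["T"], counts[off]["other"]
        coverage = c + t
        rows.append(
            dict(
                marker=amplicon.cpg_id,
                offset=off,
                kind=kind[off],
                is_target=off == amplicon.target_offset,
                c_count=c,
                t_count=t,
                other_count=other,
                coverage=coverage,
                raw_beta=(c / coverage) if coverage > 0 else np.nan,
                pass_coverage=coverage >= min_reads,
            )
        )
    return pd.DataFrame(rows)


def conversion_rate(callset: pd.DataFrame) -> float:
    """Pooled conversion rate over a marker's control offsets: T/(C+T)."""
    controls = callset[callset["kind"] == "control"]
    c = int(controls["c_count"].sum())
    t = int(controls["t_count"].sum())
    if c + t == 0:
        raise ConversionError("no conversion controls observed")
    return t / (c + t)


def correct_conversion(raw_beta: float, rate: float) -> float:
    """Invert the conversion process: corrected = (raw − (1−rate)) / rate.

    A conversion failure leaves an unmethylated C unconverted, so the
    observed C fraction is raw = m + (1−rate)(1−m); this solves for m and
    clamps to [0, 1]. Rates at or below 0.5 indicate assay failure.
    """
    if rate <= 0.5:
        raise ConversionError(f"conversion rate {rate:.3f} <= 0.5: assay failure")
    if np.isnan(raw_beta):
        return np.nan
    return float(np.clip((raw_beta - (1.0 - rate)) / rate, 0.0, 1.0))


def quantify(
    batch: list[ReadRecord],
    panel: MarkerPanel,
    min_reads: int = DEFAULT_MIN_READS,
    per_read_rate: bool = False,
) -> pd.DataFrame:
    """Full quantification: assign → call → conversion-correct → filter.

    Returns one row per (marker, offset) with counts, coverage, the
    marker's pooled conversion rate, raw and corrected betas and the
    coverage flag. With ``per_read_rate`` the conversion rate is the mean
    of per-fragment control conversion fractions instead of the pooled
    ratio.
    """
    assignment = assign_reads(batch, panel)
    frames = []
    for marker_id, amp in panel.amplicons.items():
        reads = assignment.by_marker.get(marker_id, [])
        if not reads:
            continue
        calls = call_methylation(reads, amp, min_reads=min_reads)
        try:
            if per_read_rate:
                rate = _per_fragment_rate(reads, amp)
            else:
                rate = conversion_rate(calls)
        except ConversionError:
            rate = np.nan
        calls["conversion_rate"] = rate
        calls["corrected_beta"] = [
            correct_conversion(rb, rate) if not np.isnan(rate) else np.nan
            for rb in calls["raw_beta"]
        ]
        frames.append(calls)
    if not frames:
        return pd.DataFrame(
            columns=[
                "marker", "offset", "kind", "is_target", "c_count", "t_count",
                "other_count", "coverage", "raw_beta", "pass_coverage",
                "conversion_rate", "corrected_beta",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _per_fragment_rate(reads: list[AlignedRead], amp: Amplicon) -> float:
    """Mean of per-fragment conversion fractions over control cytosines."""
    per_frag: dict[str, list[int]] = defaultdict(list)
    for read in reads:
        for off in amp.control_offsets:
            base = _offset_base(read, off)
            if base == "T":
                per_frag[read.read_id].append(1)
            elif base == "C":
                per_frag[read.read_id].append(0)
    fractions = [np.mean(v) for v in per_frag.values() if v]
    if not fractions:
        raise ConversionError("no conversion controls observed")
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------


def write_fastq(batch: list[ReadRecord], path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rec in batch:
            fh = f1 if rec.mate == 1 else f2
            fh.write(f"@{rec.read_id}/{rec.mate}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fastq(path_r1, path_r2=None) -> list[ReadRecord]:
    from Bio import SeqIO

    batch = []
    for mate, path in ((1, path_r1), (2, path_r2)):
        if path is None:
            continue
        for rec in SeqIO.parse(str(path), "fastq"):
            rid = rec.id.rsplit("/", 1)[0]
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            batch.append(ReadRecord(rid, mate, str(rec.seq).upper(), qual))
    return batch


def write_sam(assignment: Assignment, panel: MarkerPanel, path) -> None:
    """Minimal SAM export of assigned reads (single-end records per mate)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for marker_id, amp in panel.amplicons.items():
            fh.write(f"@SQ\tSN:{marker_id}\tLN:{amp.length}\n")
        for marker_id, reads in assignment.by_marker.items():
            for read in reads:
                flag = 0 if read.mate == 1 else 16
                cigar = read.cigar or f"{len(read.sequence)}="
                fh.write(
                    f"{read.read_id}/{read.mate}\t{flag}\t{marker_id}\t"
                    f"{read.ref_start + 1}\t60\t{cigar}\t*\t0\t0\t"
                    f"{read.sequence}\t*\tNM:i:{read.distance}\n"
                )
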