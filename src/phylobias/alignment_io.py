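"""Alignment input/output and preprocessing.

Reads four-species alignments (MAF or aligned multi-FASTA), drops columns
gapped in the target (reference) genome, re-partitions long alignments into
blocks whose boundaries fall in runs uninformative about the target lineage,
and writes genomic-interval (BED) and per-position posterior (WIG) tracks.

Internal coordinates are 0-based half-open throughout; WIG output converts
to the wiggle standard's 1-based positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

# Symbol encoding. 'N' doubles as "species absent from this block"; both are
# treated identically as missing data downstream.
ALPHABET = "ACGTN-"
A, C, G, T, N, GAP = range(6)
_CODE = np.full(256, N, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i

#: number of symbol states relevant to emissions (A, C, G, T, N)
N_SYMBOLS = 5


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (uppercasing; unknown -> N)."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class GenomicInterval:
    """A 0-based half-open interval on a reference sequence."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentBlock:
    """A column-indexed alignment over a fixed, ordered set of taxa.

    ``seqs`` is a (n_species, n_columns) uint8 matrix over the symbol codes;
    ``ref_coords`` gives, per column, the 0-based position on the target
    (reference) genome.  Columns may be non-contiguous after filtering, so
    ``end - start`` may exceed the number of columns.  Reference coordinates
    are strictly increasing once target-gap columns have been removed (a raw
    block assigns a target-gap column the coordinate of the next target base).
    """

    species: list[str]
    seqs: np.ndarray
    ref_coords: np.ndarray
    chrom: str = "chrSim"
    target: str = "human"

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        self.ref_coords = np.asarray(self.ref_coords, dtype=np.int64)
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.species):
            raise ValueError("seqs must be (n_species, n_columns)")
        if self.seqs.shape[1] != self.ref_coords.shape[0]:
            raise ValueError("ref_coords length must match column count")
        if self.target not in self.species:
            raise ValueError(f"target taxon {self.target!r} not in block")

    @property
    def n_columns(self) -> int:
        return self.seqs.shape[1]

    @property
    def target_row(self) -> int:
        return self.species.index(self.target)

    @property
    def start(self) -> int:
        return int(self.ref_coords[0]) if self.n_columns else 0

    @property
    def end(self) -> int:
        return int(self.ref_coords[-1]) + 1 if self.n_columns else 0

    @classmethod
    def from_strings(
        cls,
        rows: dict[str, str],
        target: str,
        chrom: str = "chrSim",
        ref_start: int = 0,
        species_order: Sequence[str] | None = None,
    ) -> "AlignmentBlock":
        """Build a block from aligned strings keyed by taxon name.

        Reference coordinates count non-gap target bases from ``ref_start``.
        """
        order = list(species_order) if species_order is not None else list(rows)
        length = {len(s) for s in rows.values()}
        if len(length) > 1:
            raise ValueError("aligned rows have unequal lengths")
        (ncol,) = length or {0}
        seqs = np.vstack(
            [
                encode(rows[sp]) if sp in rows else np.full(ncol, N, np.uint8)
                for sp in order
            ]
        ) if ncol else np.zeros((len(order), 0), np.uint8)
        tgt = seqs[order.index(target)]
        # coordinate of a target-gap column = position of the next target base
        coords = ref_start + np.cumsum(tgt != GAP) - (tgt != GAP)
        return cls(order, seqs, coords, chrom=chrom, target=target)

    def column_strings(self) -> list[str]:
        return [decode(self.seqs[i]) for i in range(len(self.species))]


# ---------------------------------------------------------------------------
# Reading


def _maf_species(src: str) -> str:
    """Taxon label from a MAF ``src`` field like ``hg18.chr1``."""
    return src.split(".", 1)[0]


def read_alignment(
    path: str,
    format: str,
    target: str,
    species: Sequence[str] | None = None,
) -> list[AlignmentBlock]:
    """Read a MAF or aligned multi-FASTA file into alignment blocks.

    Rows are reordered to a canonical taxon order (``species`` if given,
    otherwise the order of first appearance).  MAF blocks lacking one of the
    canonical taxa keep their column count, with the missing row filled with
    'N'.  Reference coordinates come from the target row's MAF coordinates;
    FASTA input is assigned coordinates 0..L-1 on a synthetic chromosome.
    Lowercase (soft-masked) bases are uppercased and retained.
    """
    if format == "maf":
        return _read_maf(path, target, species)
    if format == "fasta":
        return [_read_fasta(path, target, species)]
    raise ValueError(f"unknown alignment format: {format!r}")


def _read_maf(
    path: str, target: str, species: Sequence[str] | None
) -> list[AlignmentBlock]:
    try:
        msas = list(AlignIO.parse(path, "maf"))
    except ValueError as exc:
        raise ValueError(f"malformed MAF {path}: {exc}") from exc
    if species is None:
        seen: list[str] = []
        for msa in msas:
            for rec in msa:
                sp = _maf_species(rec.id)
                if sp not in seen:
                    seen.append(sp)
        species = seen
    order = list(species)
    if target not in order:
        raise ValueError(f"target taxon {target!r} absent from {path}")

    blocks: list[AlignmentBlock] = []
    for i, msa in enumerate(msas):
        recs = {_maf_species(rec.id): rec for rec in msa}
        if target not in recs:
            logger.warning("MAF block %d lacks target %s; skipped", i, target)
            continue
        trec = recs[target]
        if int(trec.annotations.get("strand", 1)) != 1:
            raise ValueError(f"MAF block {i}: target row on minus strand")
        chrom = trec.id.split(".", 1)[1] if "." in trec.id else trec.id
        ncol = msa.get_alignment_length()
        seqs = np.vstack(
            [
                encode(str(recs[sp].seq)) if sp in recs
                else np.full(ncol, N, np.uint8)
                for sp in order
            ]
        )
        tgt = seqs[order.index(target)]
        start = int(trec.annotations["start"])
        coords = start + np.cumsum(tgt != GAP) - (tgt != GAP)
        blocks.append(
            AlignmentBlock(order, seqs, coords, chrom=chrom, target=target)
        )
    if not blocks:
        raise ValueError(f"target taxon {target!r} absent from all blocks")
    return blocks


def _read_fasta(
    path: str, target: str, species: Sequence[str] | None
) -> AlignmentBlock:
    try:
        msa = AlignIO.read(path, "fasta")
    except ValueError as exc:
        raise ValueError(f"malformed FASTA alignment {path}: {exc}") from exc
    rows = {rec.id: str(rec.seq) for rec in msa}
    order = list(species) if species is not None else list(rows)
    if target not in rows:
        raise ValueError(f"target taxon {target!r} absent from {path}")
    return AlignmentBlock.from_strings(
        rows, target, chrom="chrSim", species_order=order
    )


# ---------------------------------------------------------------------------
# Preprocessing


def drop_target_gap_columns(block: AlignmentBlock) -> AlignmentBlock:
    """Remove columns gapped in the target row, and all-gap columns.

    Idempotent; reference coordinates of surviving columns are preserved.
    """
    tgt = block.seqs[block.target_row]
    keep = (tgt != GAP) & ~(block.seqs == GAP).all(axis=0)
    return replace(
        block, seqs=block.seqs[:, keep], ref_coords=block.ref_coords[keep]
    )


def mask_positions(
    block: AlignmentBlock, positions: Iterable[int]
) -> AlignmentBlock:
    """Replace the target-row symbol with 'N' at the given reference positions.

    Positions absent from the block are ignored; other rows are untouched.
    """
    pos = np.fromiter(positions, dtype=np.int64, count=-1)
    seqs = block.seqs.copy()
    hit = np.isin(block.ref_coords, pos)
    seqs[block.target_row, hit] = N
    return replace(block, seqs=seqs)


def uninformative_runs(block: AlignmentBlock, min_run: int) -> list[tuple[int, int]]:
    """Column index ranges spanning >= min_run reference bp where every
    non-target row is missing ('N')."""
    others = [i for i in range(len(block.species)) if i != block.target_row]
    missing = (block.seqs[others] >= N).all(axis=0)
    runs = []
    i = 0
    L = block.n_columns
    while i < L:
        if missing[i]:
            j = i
            while j + 1 < L and missing[j + 1]:
                j += 1
            span = block.ref_coords[j] - block.ref_coords[i] + 1
            if span >= min_run:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def partition_blocks(
    blocks: list[AlignmentBlock],
    block_size: int = 10_000_000,
    min_uninformative_run: int = 1000,
) -> list[AlignmentBlock]:
    """Re-cut concatenated alignment data into ~block_size reference-bp pieces.

    Cut points must fall inside runs of at least ``min_uninformative_run``
    reference bp in which all non-target rows are missing, so no block
    boundary can split a detectable tract.  If no legal cut exists within
    +/-50% of a nominal boundary, the nearest legal cut is used; with no legal
    cut at all the data are left as one longer block (with a warning).
    Total column count is conserved.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    out: list[AlignmentBlock] = []
    for chrom, merged in _concat_by_chrom(blocks):
        out.extend(
            _cut_block(merged, block_size, min_uninformative_run)
        )
    return out


def _concat_by_chrom(blocks):
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        if len(bs) == 1:
            yield chrom, bs[0]
        else:
            yield chrom, replace(
                bs[0],
                seqs=np.concatenate([b.seqs for b in bs], axis=1),
                ref_coords=np.concatenate([b.ref_coords for b in bs]),
            )


def _cut_block(block, block_size, min_run):
    span = block.end - block.start
    if span <= block_size:
        return [block]
    runs = uninformative_runs(block, min_run)
    # candidate cut columns: middle of each qualifying run
    cut_cols = np.array([(i + j) // 2 for i, j in runs], dtype=np.int64)
    if cut_cols.size == 0:
        warnings.warn(
            f"{block.chrom}: no uninformative run >= {min_run} bp; "
            "left as a single block"
        )
        return [block]
    cut_pos = block.ref_coords[cut_cols]
    pieces = []
    lo = 0  # first column of the current piece
    while block.ref_coords[-1] - block.ref_coords[lo] + 1 > block_size * 1.5:
        nominal = block.ref_coords[lo] + block_size
        cand = cut_cols[(cut_pos > block.ref_coords[lo]) & (cut_cols > lo)]
        if cand.size == 0:
            break
        dist = np.abs(block.ref_coords[cand] - nominal)
        best = cand[int(np.argmin(dist))]
        pieces.append((lo, best))
        lo = best
    pieces.append((lo, block.n_columns))
    return [
        replace(
            block,
            seqs=block.seqs[:, i:j],
            ref_coords=block.ref_coords[i:j],
        )
        for i, j in pieces
        if j > i
    ]


# ---------------------------------------------------------------------------
# Writing

_PROVENANCE = "# phylobias"


def write_tracts_bed(
    tracts: Sequence[GenomicInterval], path: str, header: str | None = None
) -> None:
    """Write intervals as BED4/BED5 (0-based half-open); input must be sorted."""
    keys = [(t.chrom, t.start) for t in tracts]
    if keys != sorted(keys):
        raise ValueError("tracts must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        fh.write(f'track name=gBGC_tracts description="{header or "gBGC tracts"}"\n')
        for i, t in enumerate(tracts):
            line = f"{t.chrom}\t{t.start}\t{t.end}\ttract_{i + 1}"
            if t.score is not None:
                line += f"\t{t.score:.4f}"
            fh.write(line + "\n")


def write_posterior_wig(
    ref_coords: np.ndarray,
    posterior: np.ndarray,
    chrom: str,
    path: str,
) -> None:
    """Write per-position posteriors as variableStep WIG (1-based positions)."""
    posterior = np.asarray(posterior, dtype=float)
    if posterior.size and (posterior.min() < 0 or posterior.max() > 1):
        raise ValueError("posterior values must lie in [0, 1]")
    with open(path, "w") as fh:
        fh.write('track type=wiggle_0 name="P(gBGC)"\n')
        fh.write(f"variableStep chrom={chrom}\n")
        for pos, p in zip(np.asarray(ref_coords) + 1, posterior):
            fh.write(f"{pos}\t{p:.4f}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ intervals (track/comment lines skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            score = float(f[4]) if len(f) > 4 else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), score))
    return out


def write_fasta(block: AlignmentBlock, path: str) -> None:
    with open(path, "w") as fh:
        for sp, row in zip(block.species, block.column_strings()):
            fh.write(f">{sp}\n")
            for i in range(0, len(row), 80):
                fh.write(row[i : i + 80] + "\n")


def write_maf(block: AlignmentBlock, path: str, seed_note: str | None = None) -> None:
    """Write one block as MAF (target coordinates from ref_coords)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        if seed_note:
            fh.write(f"# {seed_note}\n")
        fh.write("\na score=0.0\n")
        for sp, row in zip(block.species, block.column_strings()):
            n_bases = sum(ch != "-" for ch in row)
            start = block.start if sp == block.target else 0
            src = f"{sp}.{block.chrom}" if sp == block.target else f"{sp}.scaf"
            fh.write(f"s {src} {start} {n_bases} + {start + n_bases} {row}\n")
        fh.write("\n")
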