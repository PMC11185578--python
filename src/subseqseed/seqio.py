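"""FASTA input and TSV serialization of seeds, matches and truth alignments.

Seeds are exchanged as a plain TSV (header required) with columns
``seq_id, window_start, order_index, seed, positions, psi, omega`` where
``positions`` is a comma-joined strictly increasing list of window-relative
offsets.  TSV keeps the outputs human-diffable, which matters more than
compactness at the scales this tool targets.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

from Bio import SeqIO

from .matching import GroundTruthAlignment
from .reference import ScorePair, Seed

__all__ = ["read_fasta", "write_seeds", "read_seeds",
           "write_truth", "read_truth"]

SEED_COLUMNS = ("seq_id", "window_start", "order_index", "seed",
                "positions", "psi", "omega")


class SeedFileError(ValueError):
    """Raised for malformed seed TSV files."""


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file, transparently gunzipping
    paths ending in .gz.  Ids are the first whitespace token of the header;
    sequences are uppercased."""
    path = str(path)
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq).upper()
    finally:
        handle.close()


def write_seeds(seeds: Iterable[Seed], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEED_COLUMNS) + "\n")
        for s in seeds:
            fh.write("\t".join((s.seq_id, str(s.window_start), str(s.order_index),
                                s.seed, ",".join(map(str, s.positions)),
                                str(s.score.psi), str(s.score.omega))) + "\n")


def read_seeds(path) -> list[Seed]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != list(SEED_COLUMNS):
            raise SeedFileError(f"{path}: bad or missing header {header!r}")
        out = []
        for row_no, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(SEED_COLUMNS):
                raise SeedFileError(f"{path}: row {row_no}: expected "
                                    f"{len(SEED_COLUMNS)} fields, got {len(fields)}")
            sid, ws, oi, seed, pos_s, psi, omega = fields
            try:
                positions = tuple(int(p) for p in pos_s.split(","))
                rec = Seed(seq_id=sid, window_start=int(ws), order_index=int(oi),
                           seed=seed, positions=positions,
                           score=ScorePair(int(psi), int(omega)))
            except ValueError as exc:
                raise SeedFileError(f"{path}: row {row_no}: {exc}") from None
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise SeedFileError(f"{path}: row {row_no}: positions not "
                                    f"strictly increasing: {pos_s}")
            out.append(rec)
    return out


def write_truth(truth: GroundTruthAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos_a\tpos_b\n")
        for a, b in truth.pairs:
            fh.write(f"{a}\t{b}\n")


def read_truth(path) -> GroundTruthAlignment:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["pos_a", "pos_b"]:
            raise SeedFileError(f"{path}: bad truth header {header!r}")
        for row_no, line in enumerate(fh, start=2):
            a, b = line.rstrip("\n").split("\t")
            pairs.append((int(a), int(b)))
    return GroundTruthAlignment(tuple(pairs))
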