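"""Score tables defining the k pivot-split orders over length-k strings.

A table set is governed by an integer modulus ``d`` and nine tables: forward
tables (AF, BF, CF) feeding a left-to-right score recurrence, reverse tables
(AR, BR, CR) feeding a right-to-left recurrence, and pivot tables (AP, BP, CP)
that combine the two halves around a pivot character.  Filling the tables with
random values yields k pseudo-random total orders over the length-k strings;
filling them with paired constraints yields orders in which a string and its
reverse complement receive corresponding ranks (the reverse-complement-symmetric
variant).

Internally everything is 0-based: order index ``i`` runs over ``0..k-1`` and
table row ``l`` is the 0-based position of a character within a (sub)sequence.
The 1-based order index used in user-facing output lives only at the I/O layer.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "ABCkTables",
    "make_random_tables",
    "make_rc_symmetric_tables",
    "validate_rc_symmetry",
    "save_tables",
    "load_tables",
    "example_tables",
    "DNA_ALPHABET",
    "MAX_D",
]

DNA_ALPHABET = ("A", "C", "G", "T")
#: complement partner index within DNA_ALPHABET: A<->T, C<->G
DNA_COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.int64)
MAX_D = 32

_FORMAT_VERSION = 1
_SIGN_PAIRS = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=np.int64)


class TableParameterError(ValueError):
    """Raised for invalid (k, d, alphabet, value-range) parameters."""


class TableFormatError(ValueError):
    """Raised when a table file cannot be parsed or fails validation."""


@dataclasses.dataclass
class ABCkTables:
    """The nine score tables plus (k, d, alphabet) defining k orders.

    Shapes (s = alphabet size):

    ============ ============== =========================================
    field        shape          entries
    ============ ============== =========================================
    AF, AR       (k, d, s)      magnitudes, default range [10, 100]
    BF1/BF2,
    BR1/BR2      (k, d, s)      signs in {+1, -1} (pair split per component)
    AP           (k, s)         magnitudes in [-100, -10] | [10, 100]
    BP1, BP2     (k, s)         signs in {+1, -1}
    CF, CR, CP   (k, s)         residues in [0, d)
    ============ ============== =========================================
    """

    k: int
    d: int
    alphabet: tuple[str, ...]
    AF: np.ndarray
    AR: np.ndarray
    BF1: np.ndarray
    BF2: np.ndarray
    BR1: np.ndarray
    BR2: np.ndarray
    AP: np.ndarray
    BP1: np.ndarray
    BP2: np.ndarray
    CF: np.ndarray
    CR: np.ndarray
    CP: np.ndarray
    rc_symmetric: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.alphabet = tuple(self.alphabet)
        for name in ("AF", "AR", "BF1", "BF2", "BR1", "BR2",
                     "AP", "BP1", "BP2", "CF", "CR", "CP"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), dtype=np.int64))
        self.validate()

    # -- basic structure -------------------------------------------------

    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    def symbol_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.alphabet)}

    def encode(self, s: str) -> np.ndarray:
        """Map a string to alphabet codes; unknown symbols become -1."""
        lut = np.full(256, -1, dtype=np.int8)
        for i, c in enumerate(self.alphabet):
            lut[ord(c)] = i
            lut[ord(c.lower())] = i
        return lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]

    def decode(self, codes: Sequence[int]) -> str:
        return "".join(self.alphabet[c] for c in codes)

    def validate(self) -> None:
        k, d, s = self.k, self.d, self.sigma
        if k < 1:
            raise TableParameterError(f"k must be >= 1, got {k}")
        if not 1 <= d <= MAX_D:
            raise TableParameterError(f"d must be in [1, {MAX_D}], got {d}")
        if s < 1:
            raise TableParameterError("alphabet must be non-empty")
        shapes = {"AF": (k, d, s), "AR": (k, d, s), "BF1": (k, d, s),
                  "BF2": (k, d, s), "BR1": (k, d, s), "BR2": (k, d, s),
                  "AP": (k, s), "BP1": (k, s), "BP2": (k, s),
                  "CF": (k, s), "CR": (k, s), "CP": (k, s)}
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise TableParameterError(f"{name} has shape {arr.shape}, expected {shape}")
        for name in ("BF1", "BF2", "BR1", "BR2", "BP1", "BP2"):
            if not np.isin(getattr(self, name), (-1, 1)).all():
                raise TableParameterError(f"{name} entries must be +1 or -1")
        for name in ("CF", "CR", "CP"):
            arr = getattr(self, name)
            if arr.min() < 0 or arr.max() >= d:
                raise TableParameterError(f"{name} entries must lie in [0, {d})")

    def equals(self, other: "ABCkTables") -> bool:
        if (self.k, self.d, self.alphabet, self.rc_symmetric, self.rng_seed) != (
                other.k, other.d, other.alphabet, other.rc_symmetric, other.rng_seed):
            return False
        return all(np.array_equal(getattr(self, n), getattr(other, n))
                   for n in ("AF", "AR", "BF1", "BF2", "BR1", "BR2",
                             "AP", "BP1", "BP2", "CF", "CR", "CP"))


def _check_params(k: int, d: int, alphabet: Sequence[str]) -> None:
    if k < 1:
        raise TableParameterError(f"k must be >= 1, got {k}")
    if not 1 <= d <= MAX_D:
        raise TableParameterError(f"d must be in [1, {MAX_D}], got {d}")
    if len(alphabet) < 1:
        raise TableParameterError("alphabet must be non-empty")


def _random_magnitudes(rng: np.random.Generator, shape, lo: int, hi: int,
                       signed: bool) -> np.ndarray:
    mags = rng.integers(lo, hi + 1, size=shape, dtype=np.int64)
    if signed:
        signs = rng.choice((-1, 1), size=shape)
        mags = mags * signs
    return mags


def _random_sign_pairs(rng: np.random.Generator, shape) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, 4, size=shape)
    return _SIGN_PAIRS[idx, 0], _SIGN_PAIRS[idx, 1]


def make_random_tables(k: int, d: int, rng_seed: int,
                       alphabet: Sequence[str] = DNA_ALPHABET,
                       a_range: tuple[int, int] = (10, 100)) -> ABCkTables:
    """Draw a fully random table set.

    AF/AR magnitudes are drawn from ``a_range`` (default [10, 100]); AP from
    the signed union [-hi, -lo] | [lo, hi]; B entries uniformly from the four
    sign pairs; C entries uniformly from [0, d).  Deterministic given
    ``rng_seed``.
    """
    _check_params(k, d, alphabet)
    lo, hi = a_range
    if not 0 < lo <= hi:
        raise TableParameterError(f"invalid magnitude range {a_range}")
    s = len(alphabet)
    rng = np.random.default_rng(rng_seed)
    AF = _random_magnitudes(rng, (k, d, s), lo, hi, signed=False)
    AR = _random_magnitudes(rng, (k, d, s), lo, hi, signed=False)
    AP = _random_magnitudes(rng, (k, s), lo, hi, signed=True)
    BF1, BF2 = _random_sign_pairs(rng, (k, d, s))
    BR1, BR2 = _random_sign_pairs(rng, (k, d, s))
    BP1, BP2 = _random_sign_pairs(rng, (k, s))
    CF = rng.integers(0, d, size=(k, s), dtype=np.int64)
    CR = rng.integers(0, d, size=(k, s), dtype=np.int64)
    CP = rng.integers(0, d, size=(k, s), dtype=np.int64)
    return ABCkTables(k=k, d=d, alphabet=tuple(alphabet),
                      AF=AF, AR=AR, BF1=BF1, BF2=BF2, BR1=BR1, BR2=BR2,
                      AP=AP, BP1=BP1, BP2=BP2, CF=CF, CR=CR, CP=CP,
                      rc_symmetric=False, rng_seed=int(rng_seed))


def make_rc_symmetric_tables(k: int, d: int, rng_seed: int,
                             a_range: tuple[int, int] = (10, 100)) -> ABCkTables:
    """Draw tables constrained so a string and its reverse complement get
    corresponding scores: pi(z, i) == pi(revcomp(z), k-1-i) for every z, i.

    One half of each constrained pair is drawn randomly and the other half is
    derived.  DNA alphabet only (the complement map A<->T, C<->G is built in).
    The construction is well-defined for odd k: the self-paired middle order
    only constrains symbols against their complements, never against
    themselves.
    """
    t = make_random_tables(k, d, rng_seed, DNA_ALPHABET, a_range)
    comp = DNA_COMPLEMENT_INDEX
    # reverse tables fully derived from forward ones: X_R[l][z] = X_F[l][zbar]
    AR = t.AF[:, :, comp].copy()
    BR1 = t.BF1[:, :, comp].copy()
    BR2 = t.BF2[:, :, comp].copy()
    CR = t.CF[:, comp].copy()
    # pivot tables: rows i and k-1-i paired through the complement map
    AP, BP1, BP2, CP = t.AP.copy(), t.BP1.copy(), t.BP2.copy(), t.CP.copy()
    for i in range(k):
        m = k - 1 - i
        if i > m:
            continue
        if i == m:
            # middle row: derive G, T from C, A (z and zbar never coincide)
            for z in (0, 1):  # A, C
                zb = comp[z]
                CP[i, zb] = CP[i, z]
                AP[i, zb] = AP[i, z]
                BP1[i, zb] = BP2[i, z]
                BP2[i, zb] = BP1[i, z]
        else:
            CP[m] = CP[i][comp]
            AP[m] = AP[i][comp]
            BP1[m] = BP2[i][comp]
            BP2[m] = BP1[i][comp]
    return ABCkTables(k=k, d=d, alphabet=DNA_ALPHABET,
                      AF=t.AF, AR=AR, BF1=t.BF1, BF2=t.BF2, BR1=BR1, BR2=BR2,
                      AP=AP, BP1=BP1, BP2=BP2, CF=t.CF, CR=CR, CP=CP,
                      rc_symmetric=True, rng_seed=int(rng_seed))


def validate_rc_symmetry(tables: ABCkTables) -> list[str]:
    """Return the list of reverse-complement constraint violations (empty iff
    the tables are symmetric).  Each violation names the table, the indices
    (1-based order index, residue, symbol) and the two unequal values."""
    if tables.alphabet != DNA_ALPHABET:
        return [f"alphabet {tables.alphabet} has no complement map"]
    comp = DNA_COMPLEMENT_INDEX
    sym = tables.alphabet
    out: list[str] = []
    k = tables.k
    for i in range(k):
        m = k - 1 - i
        for z in range(4):
            zb = comp[z]
            pairs = [
                ("CP", tables.CP[m, z], tables.CP[i, zb]),
                ("AP", tables.AP[m, z], tables.AP[i, zb]),
                ("BP[.]1 vs BP[.]2", tables.BP1[m, z], tables.BP2[i, zb]),
                ("BP[.]2 vs BP[.]1", tables.BP2[m, z], tables.BP1[i, zb]),
                ("CF vs CR", tables.CF[i, z], tables.CR[i, zb]),
            ]
            for name, a, b in pairs:
                if a != b:
                    out.append(f"{name}: i={i + 1}, sigma={sym[z]}: {a} != {b}")
            for j in range(tables.d):
                trips = [
                    ("AF vs AR", tables.AF[i, j, z], tables.AR[i, j, zb]),
                    ("BF1 vs BR1", tables.BF1[i, j, z], tables.BR1[i, j, zb]),
                    ("BF2 vs BR2", tables.BF2[i, j, z], tables.BR2[i, j, zb]),
                ]
                for name, a, b in trips:
                    if a != b:
                        out.append(f"{name}: i={i + 1}, j={j}, sigma={sym[z]}: {a} != {b}")
    return out


# -- serialization -------------------------------------------------------
#
# Self-describing text format: a version line, a header with (k, d, alphabet,
# rc_symmetric, rng_seed), then each table as labelled integer rows.

def save_tables(tables: ABCkTables, path) -> None:
    lines = [f"subseqseed-tables v{_FORMAT_VERSION}",
             f"k {tables.k}",
             f"d {tables.d}",
             f"alphabet {''.join(tables.alphabet)}",
             f"rc_symmetric {int(tables.rc_symmetric)}",
             f"rng_seed {tables.rng_seed}"]
    for name in ("AF", "AR", "BF1", "BF2", "BR1", "BR2"):
        arr = getattr(tables, name)
        for i in range(tables.k):
            for j in range(tables.d):
                row = " ".join(str(v) for v in arr[i, j])
                lines.append(f"{name} {i} {j} {row}")
    for name in ("AP", "BP1", "BP2", "CF", "CR", "CP"):
        arr = getattr(tables, name)
        for i in range(tables.k):
            row = " ".join(str(v) for v in arr[i])
            lines.append(f"{name} {i} {row}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_header_line(lines: list[str], idx: int, key: str) -> str:
    if idx >= len(lines):
        raise TableFormatError(f"truncated file: missing '{key}' header line")
    parts = lines[idx].split()
    if len(parts) != 2 or parts[0] != key:
        raise TableFormatError(f"line {idx + 1}: expected '{key} <value>', got {lines[idx]!r}")
    return parts[1]


def load_tables(path) -> ABCkTables:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableFormatError("empty table file")
    head = lines[0].split()
    if len(head) != 2 or head[0] != "subseqseed-tables":
        raise TableFormatError(f"line 1: not a subseqseed table file: {lines[0]!r}")
    if head[1] != f"v{_FORMAT_VERSION}":
        raise TableFormatError(f"unsupported table file version {head[1]!r} "
                               f"(this build reads v{_FORMAT_VERSION})")
    k = int(_parse_header_line(lines, 1, "k"))
    d = int(_parse_header_line(lines, 2, "d"))
    alphabet = tuple(_parse_header_line(lines, 3, "alphabet"))
    rc_symmetric = bool(int(_parse_header_line(lines, 4, "rc_symmetric")))
    rng_seed = int(_parse_header_line(lines, 5, "rng_seed"))
    try:
        _check_params(k, d, alphabet)
    except TableParameterError as exc:
        raise TableFormatError(f"invalid header values: {exc}") from exc
    s = len(alphabet)
    arrs3 = {n: np.zeros((k, d, s), dtype=np.int64)
             for n in ("AF", "AR", "BF1", "BF2", "BR1", "BR2")}
    arrs2 = {n: np.zeros((k, s), dtype=np.int64)
             for n in ("AP", "BP1", "BP2", "CF", "CR", "CP")}
    seen3 = {n: np.zeros((k, d), dtype=bool) for n in arrs3}
    seen2 = {n: np.zeros(k, dtype=bool) for n in arrs2}
    for ln_no, line in enumerate(lines[6:], start=7):
        parts = line.split()
        name = parts[0]
        try:
            if name in arrs3:
                i, j = int(parts[1]), int(parts[2])
                vals = [int(v) for v in parts[3:]]
                if len(vals) != s or not (0 <= i < k and 0 <= j < d):
                    raise ValueError
                arrs3[name][i, j] = vals
                seen3[name][i, j] = True
            elif name in arrs2:
                i = int(parts[1])
                vals = [int(v) for v in parts[2:]]
                if len(vals) != s or not 0 <= i < k:
                    raise ValueError
                arrs2[name][i] = vals
                seen2[name][i] = True
            else:
                raise ValueError
        except (ValueError, IndexError):
            raise TableFormatError(f"line {ln_no}: malformed table row {line!r}") from None
    missing = [n for n, m in seen3.items() if not m.all()]
    missing += [n for n, m in seen2.items() if not m.all()]
    if missing:
        raise TableFormatError(f"truncated file: incomplete tables {sorted(missing)}")
    try:
        return ABCkTables(k=k, d=d, alphabet=alphabet, rc_symmetric=rc_symmetric,
                          rng_seed=rng_seed, **arrs3, **arrs2)
    except TableParameterError as exc:
        raise TableFormatError(f"invalid table values: {exc}") from exc


def example_tables() -> ABCkTables:
    """The packaged worked-example table set (k=6, d=5, random fill).

    A small, fixed instance convenient for hand-checkable score evaluations
    in tests and documentation; it is a plain random table set and is *not*
    reverse-complement symmetric.
    """
    import importlib.resources as res
    with res.as_file(res.files("subseqseed.data") / "example_k6_d5.tables") as p:
        return load_tables(p)
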