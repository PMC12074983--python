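"""Ternary combinatorial FISH barcodes: code space, sequence assembly,
trit calling from round/channel intensities, and error-correcting decoding.

A cell identity is a 10-digit ternary barcode ("trit code"): each of ten
sequential imaging rounds reads one digit whose value (0, 1 or 2) is
reported by one of three fluorescence channels. Decoding matches the
called code against a sequencing-derived codebook of "good" codes
(uniquely paired with one sgRNA) and "bad" codes (paired with several),
optionally correcting up to ``max_correction`` miscalled digits.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Sentinel for a digit whose channel call did not pass the confidence filter.
UNCALLED: int = -1

#: Default barcode geometry.
N_DIGITS = 10
N_VALUES = 3
DIGIT_SEGMENT_NT = 41
DIGIT_SEPARATOR = "C"

#: Secondary-probe fluorophores read out per digit value.
DEFAULT_CHANNELS = ("ATTO565", "AF647", "AF750")

TritCode = tuple  # tuple[int, ...], values in {0, 1, 2} or UNCALLED


class CodecError(ValueError):
    """Invalid argument to a barcode operation."""


class CodebookError(RuntimeError):
    """Codebook unusable for decoding (e.g. empty)."""


def code_from_string(s: str) -> TritCode:
    """Parse a code string like ``"0120211002"``; ``?`` marks an uncalled digit."""
    digits = []
    for ch in s:
        if ch == "?":
            digits.append(UNCALLED)
        else:
            v = int(ch)
            if not 0 <= v <= 9:
                raise CodecError(f"bad digit {ch!r} in code string")
            digits.append(v)
    return tuple(digits)


def code_to_string(code: Sequence[int]) -> str:
    return "".join("?" if d == UNCALLED else str(d) for d in code)


def validate_code(code: Sequence[int], n_digits: int = N_DIGITS,
                  n_values: int = N_VALUES) -> TritCode:
    code = tuple(int(d) for d in code)
    if len(code) != n_digits:
        raise CodecError(f"code has {len(code)} digits, expected {n_digits}")
    for d in code:
        if d != UNCALLED and not 0 <= d < n_values:
            raise CodecError(f"digit value {d} outside 0..{n_values - 1}")
    return code


# ---------------------------------------------------------------------------
# Code space
# ---------------------------------------------------------------------------

def enumerate_code_space(n_digits: int, n_values: int) -> int:
    """Number of distinct codes in the combinatorial space (n_values**n_digits).

    The default 10-trit design spans 3**10 = 59,049 codes.
    """
    if n_digits < 1 or n_values < 2:
        raise CodecError("need n_digits >= 1 and n_values >= 2")
    return n_values ** n_digits


def iter_code_space(n_digits: int, n_values: int) -> Iterator[TritCode]:
    """Yield every code in the space exactly once (lexicographic order)."""
    if n_digits < 1 or n_values < 2:
        raise CodecError("need n_digits >= 1 and n_values >= 2")
    return itertools.product(range(n_values), repeat=n_digits)


def int_to_code(x: int, n_digits: int = N_DIGITS, n_values: int = N_VALUES) -> TritCode:
    """Index -> code, big-endian base-``n_values`` expansion."""
    digits = []
    for _ in range(n_digits):
        digits.append(x % n_values)
        x //= n_values
    return tuple(reversed(digits))


# ---------------------------------------------------------------------------
# Digit library and sequence assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigitLibrary:
    """Per (digit, value): a 41-nt segment (two 20-nt hybridization sequences
    joined by a 1-nt spacer), its linear/padlock probe pair, and the
    secondary-probe channel that reports the value."""

    n_digits: int
    n_values: int
    segments: Mapping[tuple, str]        # (digit, value) -> 41-nt sequence
    probe_pairs: Mapping[tuple, tuple]   # (digit, value) -> (linear_id, padlock_id)
    channels: tuple = DEFAULT_CHANNELS   # value -> channel name

    def __post_init__(self):
        expect = self.n_digits * self.n_values
        if len(self.segments) != expect:
            raise CodecError(f"digit library has {len(self.segments)} segments, expected {expect}")
        if len(set(self.channels)) != self.n_values:
            raise CodecError("the values of one digit must map to distinct channels")

    @property
    def n_probes(self) -> int:
        """Total hybridization probes: one linear + one padlock per (digit, value)."""
        return 2 * len(self.probe_pairs)

    def segment(self, digit: int, value: int) -> str:
        return self.segments[(digit, value)]

    def channel_for_value(self, value: int) -> str:
        return self.channels[value]

    @classmethod
    def default(cls, n_digits: int = N_DIGITS, n_values: int = N_VALUES,
                seed: int = 20240101) -> "DigitLibrary":
        """Synthetic library with the default geometry: 30 (digit, value)
        entries, 41-nt segments, 60 probes. Sequences are random stand-ins
        for the screen's designed orthogonal 20-mers."""
        rng = np.random.default_rng(seed)
        alphabet = np.array(list("ACGT"))
        segments, pairs = {}, {}
        for d in range(n_digits):
            for v in range(n_values):
                left = "".join(rng.choice(alphabet, 20))
                right = "".join(rng.choice(alphabet, 20))
                segments[(d, v)] = left + DIGIT_SEPARATOR + right
                pairs[(d, v)] = (f"linear_d{d + 1}_v{v}", f"padlock_d{d + 1}_v{v}")
        return cls(n_digits, n_values, segments, pairs)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=f"digit{d + 1}_value{v}", description="")
            for (d, v), seq in sorted(self.segments.items())
        ]
        seqio_write(records, str(path), "fasta")


def assemble_barcode_sequence(code: Sequence[int], lib: DigitLibrary) -> str:
    """Concatenate the chosen 41-nt digit segments, one 'C' between adjacent
    digits; the default 10-digit body is 10*41 + 9 = 419 nt."""
    code = validate_code(code, lib.n_digits, lib.n_values)
    if any(d == UNCALLED for d in code):
        raise CodecError("cannot assemble a sequence from a code with uncalled digits")
    return DIGIT_SEPARATOR.join(lib.segment(i, v) for i, v in enumerate(code))


# ---------------------------------------------------------------------------
# Trit calling
# ---------------------------------------------------------------------------

def call_trits(readout: np.ndarray, min_ratio: float = 2.0):
    """Call one digit per imaging round from a (rounds x channels) intensity
    matrix.

    The called value is the brightest channel; the call confidence is the
    top-to-second intensity ratio. Rounds with confidence below
    ``min_ratio`` (or with no signal at all) are left UNCALLED.

    Returns ``(code, quality)`` where quality is a per-digit float vector
    (``inf`` when the second channel is dark, 0 for an all-dark round).
    """
    readout = np.asarray(readout, dtype=float)
    if readout.ndim != 2:
        raise CodecError("readout must be a 2-D (rounds x channels) matrix")
    if (readout < 0).any() or not np.isfinite(readout).all():
        raise CodecError("intensities must be finite and non-negative")
    if min_ratio <= 0:
        raise CodecError("min_ratio must be positive")

    order = np.argsort(readout, axis=1)
    top_idx = order[:, -1]
    top = readout[np.arange(len(readout)), top_idx]
    second = readout[np.arange(len(readout)), order[:, -2]]

    with np.errstate(divide="ignore", invalid="ignore"):
        quality = np.where(second > 0, top / second, np.where(top > 0, np.inf, 0.0))
    code = np.where(quality >= min_ratio, top_idx, UNCALLED)
    return tuple(int(d) for d in code), quality


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def trit_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Hamming distance over trits; UNCALLED positions match anything."""
    if len(a) != len(b):
        raise CodecError("codes must have equal length")
    return sum(
        1 for x, y in zip(a, b)
        if x != UNCALLED and y != UNCALLED and x != y
    )


@dataclass
class Codebook:
    """Map from good codes to sgRNA identities plus the set of ambiguous
    ("bad") codes known to project onto multiple sgRNAs."""

    good: dict          # code string -> sgRNA id
    bad: set = field(default_factory=set)

    def __post_init__(self):
        self.bad = set(self.bad)
        overlap = set(self.good) & self.bad
        if overlap:
            raise CodebookError(f"codes in both good and bad sets: {sorted(overlap)[:3]}")

    @property
    def n_good(self) -> int:
        return len(self.good)

    @property
    def n_bad(self) -> int:
        return len(self.bad)

    def sgrnas(self) -> set:
        return set(self.good.values())

    def min_pairwise_distance(self) -> int:
        codes = [code_from_string(c) for c in self.good]
        best = min(
            (trit_distance(a, b) for a, b in itertools.combinations(codes, 2)),
            default=0,
        )
        return best

    def to_json(self, path) -> None:
        payload = {"good": dict(sorted(self.good.items())), "bad": sorted(self.bad)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(good=payload["good"], bad=set(payload.get("bad", ())))


@dataclass(frozen=True)
class DecodeResult:
    status: str                      # assigned | rejected_no_match | rejected_ambiguous | rejected_bad_code
    sgrna: str | None = None
    corrected_digits: int = 0
    quality: tuple | None = None

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


def decode(called: Sequence[int], codebook: Codebook, max_correction: int = 1,
           quality: Sequence[float] | None = None) -> DecodeResult:
    """Error-correcting decode of a called (possibly partially uncalled) code.

    Policy: an exact fully-called match against a bad code is rejected
    outright (ambiguity safety precedes correction); an exact good match is
    assigned with zero corrections; otherwise all good codes within trit
    distance <= ``max_correction`` are collected, treating UNCALLED digits
    as free wildcards — a unique candidate is assigned, several reject as
    ambiguous, none as no-match. Deterministic and independent of codebook
    iteration order.
    """
    if codebook.n_good == 0:
        raise CodebookError("cannot decode against an empty codebook")
    if max_correction < 0:
        raise CodecError("max_correction must be >= 0")
    called = tuple(int(d) for d in called)
    q = tuple(float(x) for x in quality) if quality is not None else None

    if all(d != UNCALLED for d in called):
        s = code_to_string(called)
        if s in codebook.bad:
            return DecodeResult("rejected_bad_code", quality=q)
        if s in codebook.good:
            return DecodeResult("assigned", codebook.good[s], 0, q)

    hits = []
    for code_s in sorted(codebook.good):
        d = trit_distance(called, code_from_string(code_s))
        if d <= max_correction:
            hits.append((d, code_s))
    if not hits:
        return DecodeResult("rejected_no_match", quality=q)
    if len(hits) > 1:
        return DecodeResult("rejected_ambiguous", quality=q)
    d, code_s = hits[0]
    return DecodeResult("assigned", codebook.good[code_s], d, q)


def decode_readout(readout: np.ndarray, codebook: Codebook,
                   min_ratio: float = 2.0, max_correction: int = 1) -> DecodeResult:
    """Convenience: call trits then decode, carrying the quality vector."""
    called, quality = call_trits(readout, min_ratio=min_ratio)
    return decode(called, codebook, max_correction=max_correction, quality=quality)


# ---------------------------------------------------------------------------
# Minimum-distance code construction
# ---------------------------------------------------------------------------

def ternary_min_distance_codes(n_codes: int, n_digits: int = N_DIGITS,
                               seed: int = 0) -> list:
    """Sample ``n_codes`` codes with guaranteed pairwise trit distance >= 3.

    Codewords of a ternary Hamming-style linear code: the parity-check
    matrix uses ``n_digits`` distinct projective points of GF(3)^3 as
    columns, so every pair of codewords differs in at least 3 digits and
    single-digit miscalls are uniquely correctable.
    """
    if n_digits > 13:
        raise CodecError("construction supports up to 13 digits (projective points of GF(3)^3)")
    points = []
    for col in itertools.product(range(3), repeat=3):
        if col == (0, 0, 0):
            continue
        # keep one representative per projective class: first nonzero entry == 1
        first = next(c for c in col if c != 0)
        if first == 1:
            points.append(col)
    H = np.array(points[:n_digits]).T  # 3 x n_digits over GF(3)

    codewords = []
    for msg in itertools.product(range(3), repeat=n_digits):
        if (H @ np.array(msg) % 3 == 0).all():
            codewords.append(msg)
    if n_codes > len(codewords):
        raise CodecError(f"only {len(codewords)} codewords available, requested {n_codes}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(codewords), size=n_codes, replace=False)
    return [codewords[i] for i in sorted(idx)]
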