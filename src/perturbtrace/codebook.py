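"""sgRNA-barcode codebook construction from NGS read tables.

Paired-end sequencing cannot span the sgRNA-barcode-UMI cassette, so two
libraries are read: an sgRNA-UMI table and a barcode-UMI table (the
barcode arriving as two end-anchored partial codes). Associations are
recovered by joining on the shared 20-nt UMI; codes uniquely supported by
one sgRNA become "good", codes supported by several become "bad".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .barcode import UNCALLED, Codebook, DigitLibrary, code_to_string

READ_TABLE_COLUMNS = ("umi", "payload_type", "payload", "pass_qc")
PAYLOAD_TYPES = ("protospacer", "barcode_left", "barcode_right", "barcode_full")


def validate_read_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(READ_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    bad = ~table["payload_type"].isin(PAYLOAD_TYPES)
    if bad.any():
        raise ValueError(f"unknown payload_type values: {sorted(table.loc[bad, 'payload_type'].unique())}")
    return table


def quality_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged as failing read-length/quality filtering."""
    return table[table["pass_qc"].astype(bool)]


# ---------------------------------------------------------------------------
# Partial-code assembly
# ---------------------------------------------------------------------------

def assemble_partial_codes(left: str, right: str, n_digits: int = 10):
    """Assemble two end-anchored partial codes into one full code.

    ``left`` covers digits 1..len(left); ``right`` covers the last
    len(right) digits. The fragments must overlap by at least one digit and
    agree on every overlapping position; a gap, a conflict, or a non-overlap
    returns ``None`` (failure is a value, not an exception).
    """
    k, m = len(left), len(right)
    if k == 0 or m == 0 or k > n_digits or m > n_digits:
        return None
    start_right = n_digits - m  # 0-based start of the right fragment
    if start_right >= k:        # gap or merely abutting: no overlapping region
        return None
    for pos in range(start_right, k):
        if left[pos] != right[pos - start_right]:
            return None
    full = left + right[k - start_right:]
    assert len(full) == n_digits
    return tuple(int(c) for c in full)


# ---------------------------------------------------------------------------
# UMI join
# ---------------------------------------------------------------------------

def join_by_umi(sgrna_table: pd.DataFrame, barcode_table: pd.DataFrame,
                n_digits: int = 10) -> pd.DataFrame:
    """Inner-join the two read tables on their UMI.

    Returns one row per (UMI, sgRNA, code) association. UMIs present in
    only one table contribute nothing; barcode rows whose partial codes
    fail to assemble are dropped. A UMI carrying several sgRNAs or codes
    (collision / template switching) emits every combination, so the
    ambiguity propagates into good/bad classification.
    """
    sg = quality_filter(validate_read_table(sgrna_table))
    bc = quality_filter(validate_read_table(barcode_table))
    sg = sg[sg["payload_type"] == "protospacer"]

    codes = []
    for umi, grp in bc.groupby("umi", sort=False):
        lefts = grp.loc[grp["payload_type"] == "barcode_left", "payload"].tolist()
        rights = grp.loc[grp["payload_type"] == "barcode_right", "payload"].tolist()
        fulls = grp.loc[grp["payload_type"] == "barcode_full", "payload"].tolist()
        seen = set()
        for full in fulls:
            if len(full) == n_digits:
                seen.add(tuple(int(c) for c in full))
        for left in lefts:
            for right in rights:
                code = assemble_partial_codes(left, right, n_digits)
                if code is not None:
                    seen.add(code)
        for code in sorted(seen):
            codes.append((umi, code_to_string(code)))
    code_df = pd.DataFrame(codes, columns=["umi", "code"])

    sg_df = sg[["umi", "payload"]].rename(columns={"payload": "sgrna"})
    pairs = sg_df.merge(code_df, on="umi", how="inner")
    if pairs.empty:
        warnings.warn("no UMIs shared between sgRNA and barcode tables", stacklevel=2)
    return pairs[["umi", "sgrna", "code"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Good / bad classification
# ---------------------------------------------------------------------------

def classify_codes(pairs: pd.DataFrame, min_reads: int = 2) -> Codebook:
    """Classify codes by the number of sgRNAs that support them.

    An sgRNA supports a code when backed by >= ``min_reads`` UMI-distinct
    associations. Exactly one supporter -> good code; two or more -> bad
    code; codes with no supporter above threshold are excluded.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if pairs.empty:
        return Codebook(good={}, bad=set())
    dedup = pairs.drop_duplicates(subset=["umi", "sgrna", "code"])
    counts = dedup.groupby(["code", "sgrna"]).size()
    supported = counts[counts >= min_reads].reset_index(name="n_umis")

    good, bad = {}, set()
    for code, grp in supported.groupby("code"):
        if len(grp) == 1:
            good[code] = grp["sgrna"].iloc[0]
        else:
            bad.add(code)
    return Codebook(good=good, bad=bad)


# ---------------------------------------------------------------------------
# Library QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryQC:
    n_designed: int
    n_detected: int
    dropout_rate: float          # fraction in [0, 1]
    n_good_codes: int
    n_bad_codes: int
    per_sgrna_counts: dict       # sgRNA id -> number of good codes

    @property
    def dropout_pct(self) -> float:
        """Dropout as a percentage rounded to one decimal for reporting."""
        return round(100.0 * self.dropout_rate, 1)


def library_qc(codebook: Codebook, library: pd.DataFrame) -> LibraryQC:
    """Library-level QC: which designed sgRNAs surface in good codes.

    ``library`` is an sgRNA library table with an ``sgrna_id`` column.
    dropout_rate = (n_designed - n_detected) / n_designed.
    """
    designed = list(dict.fromkeys(library["sgrna_id"]))
    detected = codebook.sgrnas()
    counts = {sg: 0 for sg in designed}
    for sg in codebook.good.values():
        if sg in counts:
            counts[sg] += 1
    n_designed = len(designed)
    n_detected = sum(1 for sg in designed if sg in detected)
    rate = (n_designed - n_detected) / n_designed if n_designed else 0.0
    return LibraryQC(
        n_designed=n_designed,
        n_detected=n_detected,
        dropout_rate=rate,
        n_good_codes=codebook.n_good,
        n_bad_codes=codebook.n_bad,
        per_sgrna_counts=counts,
    )


# ---------------------------------------------------------------------------
# Optional digit-sequence rescue
# ---------------------------------------------------------------------------

def match_digit_sequence(observed: str, lib: DigitLibrary, digit: int,
                         max_edits: int = 0) -> int:
    """Map an observed 41-nt digit segment to a value.

    Default requires an exact match; ``max_edits=1`` enables an
    edit-distance-<=1 rescue of sequencing errors (off by default, and the
    match must be unique). Returns the value or UNCALLED.
    """
    exact = [v for v in range(lib.n_values) if lib.segment(digit, v) == observed]
    if len(exact) == 1:
        return exact[0]
    if max_edits <= 0:
        return UNCALLED
    import edlib

    hits = [
        v for v in range(lib.n_values)
        if edlib.align(observed, lib.segment(digit, v), k=max_edits)["editDistance"] >= 0
    ]
    return hits[0] if len(hits) == 1 else UNCALLED
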