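"""Ground-truth synthetic screen generator.

Emulates every input of the analysis stack so the pipeline is testable
end-to-end without raw data: an sgRNA library with random unique ternary
codes (the screen design: 410 targeting sgRNAs over 137 genes at 2-3 per
gene plus 10 non-targeting controls), NGS-style sgRNA-UMI and barcode-UMI
read tables, per-cell round/channel barcode readouts with trit-miscall
noise, chromatin traces with compartment-dependent clustering and
perturbation-specific distance scaling, and voxelized nuclear phantoms
(spherical vs multi-lobed, with optional bright condensates driving
intensity unevenness).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode import Codebook, code_to_string, enumerate_code_space, int_to_code
from .nucleus import NucleusImage
from .traces import CompartmentProfile

# Default screen design (the study conditions).
N_TARGETING = 410
N_CONTROLS = 10
N_GENES = 137
N_TADS = 27
TRACES_PER_CELL = (2, 4)            # inclusive range per G1 cell
NON_TARGETING_GENE = "NON_TARGETING"

# Baseline trace geometry (nm): two compartment anchor clusters plus a
# random-walk backbone, sized to give ~400-700 nm adjacent-TAD distances
# and long-range contact frequencies well inside (0, 1) at the 500-nm rule.
ANCHOR_SEPARATION_NM = 600.0
RW_STEP_SD_NM = 150.0
RW_WEIGHT = 0.7
LOCAL_SD_NM = 120.0
JITTER_SD_NM = 50.0

# Barcode readout intensity model (arbitrary units).
SIGNAL_LOG_MEAN, SIGNAL_LOG_SD = np.log(1200.0), 0.25
BACKGROUND_LOG_MEAN, BACKGROUND_LOG_SD = np.log(60.0), 0.4
ATTENUATION = 0.08

# Nuclear phantom defaults.
VOXEL_SIZE_NM = (400.0, 216.0, 216.0)      # (z, y, x); 2x-binned screen voxels
NUCLEUS_SEMI_AXES_NM = (3000.0, 4200.0, 4200.0)
BASE_INTENSITY = 1000.0
INTENSITY_NOISE_SD = 60.0
CONDENSATE_COUNT = 5
CONDENSATE_AMPLITUDE = 900.0
CONDENSATE_SIGMA_VOX = 2.5


@dataclass(frozen=True)
class EffectSpec:
    """Per-sgRNA ground-truth phenotype: multiplicative distance scale
    factors per pair class (1.0 = null) plus nuclear-shape knobs."""

    scale_adjacent: float = 1.0
    scale_aa: float = 1.0
    scale_ab: float = 1.0
    scale_bb: float = 1.0
    scale_global: float = 1.0
    sphericity_offset: float = 0.0   # < 0 -> lobed nuclei
    condensate_offset: int = 0       # added to the baseline condensate count

    def __post_init__(self):
        for f in (self.scale_adjacent, self.scale_aa, self.scale_ab,
                  self.scale_bb, self.scale_global):
            if f <= 0:
                raise ValueError("scale factors must be > 0")


@dataclass
class GroundTruth:
    library: pd.DataFrame                  # sgrna_id, gene, protospacer, is_control
    assignment: dict                       # code string -> sgRNA id (good codes)
    codebook: Codebook
    effects: dict = field(default_factory=dict)   # sgRNA id -> EffectSpec
    miscall_rate: float = 0.0
    umi_collision_rate: float = 0.0
    tad_dropout_rate: float = 0.0
    jitter_sd_nm: float = JITTER_SD_NM

    def __post_init__(self):
        if not 0 <= self.miscall_rate < 1 or not 0 <= self.tad_dropout_rate < 1:
            raise ValueError("rates must lie in [0, 1)")
        missing = set(self.assignment.values()) - set(self.library["sgrna_id"])
        if missing:
            raise ValueError(f"assigned codes reference unknown sgRNAs: {sorted(missing)[:3]}")

    def effect_for(self, sgrna: str) -> EffectSpec:
        return self.effects.get(sgrna, EffectSpec())


# ---------------------------------------------------------------------------
# Compartment profile
# ---------------------------------------------------------------------------

def default_compartment_profile(n_tad: int = N_TADS) -> CompartmentProfile:
    """Deterministic chr22-like A/B profile: a smooth alternating compartment
    score wave (A-positive), strictly increasing genomic midpoints with
    0.8-2.0 Mb spacing starting on the q arm."""
    idx = np.arange(n_tad)
    scores = 1.1 * np.sin(2 * np.pi * idx / 9.0 + 0.5) + 0.15
    scores = np.where(np.abs(scores) < 0.05, 0.05, scores)  # keep labels unambiguous
    labels = tuple("A" if s > 0 else "B" for s in scores)
    spacing_mb = np.array([1.0, 1.4, 0.8, 1.6, 1.2, 2.0])
    gaps = spacing_mb[idx[:-1] % len(spacing_mb)] * 1e6
    midpoints = 17_500_000 + np.concatenate([[0.0], np.cumsum(gaps)])
    return CompartmentProfile(labels=labels, scores=scores,
                              midpoints_bp=midpoints.astype(np.int64))


# ---------------------------------------------------------------------------
# Library and codebook
# ---------------------------------------------------------------------------

def _random_protospacer(rng) -> str:
    return "".join(rng.choice(list("ACGT"), 20))


def make_library(n_targeting: int = N_TARGETING, n_controls: int = N_CONTROLS,
                 n_genes: int = N_GENES, seed: int = 0,
                 n_digits: int = 10, n_values: int = 3,
                 planted_dropout: int = 0, planted_bad: int = 0):
    """Build the sgRNA library and its ground-truth codebook.

    Codes are sampled uniquely (without replacement) from the full
    combinatorial space; targeting sgRNAs are spread over the genes at 2-3
    per gene. ``planted_dropout`` removes that many sgRNAs from the
    codebook (library-construction dropout); ``planted_bad`` assigns extra
    codes to two sgRNAs each, making them bad codes.

    Returns ``(library, ground_truth)``.
    """
    if not 2 * n_genes <= n_targeting <= 3 * n_genes:
        raise ValueError("n_targeting must allow 2-3 sgRNAs per gene")
    rng = np.random.default_rng(seed)
    n_sgrnas = n_targeting + n_controls
    space = enumerate_code_space(n_digits, n_values)
    n_codes = n_sgrnas + planted_bad
    if n_codes > space:
        raise ValueError(f"requested {n_codes} codes but the space holds {space}")
    code_ints = rng.choice(space, size=n_codes, replace=False)
    codes = [code_to_string(int_to_code(int(x), n_digits, n_values)) for x in code_ints]

    rows = []
    n_triples = n_targeting - 2 * n_genes   # genes receiving a third sgRNA
    for g in range(n_genes):
        gene = f"GENE{g + 1:03d}"
        for k in range(3 if g < n_triples else 2):
            rows.append((f"sg{gene}_{k + 1}", gene, _random_protospacer(rng), False))
    for c in range(n_controls):
        rows.append((f"sgNT_{c + 1}", NON_TARGETING_GENE, _random_protospacer(rng), True))
    library = pd.DataFrame(rows, columns=["sgrna_id", "gene", "protospacer", "is_control"])

    sgrnas = library["sgrna_id"].tolist()
    assignment = dict(zip(codes[:n_sgrnas], sgrnas))
    dropped = set(rng.choice(sgrnas, size=planted_dropout, replace=False)) if planted_dropout else set()
    good = {c: sg for c, sg in assignment.items() if sg not in dropped}
    bad = set(codes[n_sgrnas:])
    truth = GroundTruth(
        library=library,
        assignment=assignment,
        codebook=Codebook(good=good, bad=bad),
    )
    return library, truth


# ---------------------------------------------------------------------------
# NGS read tables
# ---------------------------------------------------------------------------

def make_read_tables(truth: GroundTruth, umis_per_pair: int = 12,
                     collision_rate: float = 0.0, seed: int = 0,
                     split: tuple = (6, 4)):
    """Simulate the two sequencing libraries joined by the shared UMI.

    Each detected (code, sgRNA) pair emits ``umis_per_pair`` UMIs; every
    UMI appears once in the sgRNA-UMI table (protospacer payload carries
    the sgRNA id — protospacer validation is upstream of the join) and as
    a left/right partial-code pair in the barcode-UMI table, split after
    digit ``split[0]`` with ``split[1]`` digits of overlap. A fraction
    ``collision_rate`` of UMIs is reused by a second random pair.
    """
    rng = np.random.default_rng(seed)
    pairs = sorted(truth.codebook.good.items())
    for code in sorted(truth.codebook.bad):
        # bad codes: reads from every sgRNA the code projects to
        for sg in sorted(truth.library["sgrna_id"].sample(2, random_state=int(rng.integers(2**31)))):
            pairs.append((code, sg))

    bases = np.array(list("ACGT"))
    sg_rows, bc_rows = [], []
    cut, overlap = split
    all_pairs = []
    for code, sg in pairs:
        for _ in range(umis_per_pair):
            all_pairs.append((code, sg))
    umis = ["".join(rng.choice(bases, 20)) for _ in all_pairs]

    def emit(umi, code, sg):
        sg_rows.append((umi, "protospacer", sg, True))
        bc_rows.append((umi, "barcode_left", code[:cut], True))
        bc_rows.append((umi, "barcode_right", code[cut - overlap:], True))

    for umi, (code, sg) in zip(umis, all_pairs):
        emit(umi, code, sg)
        if collision_rate and rng.random() < collision_rate:
            other_code, other_sg = pairs[rng.integers(len(pairs))]
            emit(umi, other_code, other_sg)

    cols = ["umi", "payload_type", "payload", "pass_qc"]
    return pd.DataFrame(sg_rows, columns=cols), pd.DataFrame(bc_rows, columns=cols)


# ---------------------------------------------------------------------------
# Barcode readouts
# ---------------------------------------------------------------------------

def corrupt_one_trit(code, rng, n_values: int = 3):
    """Flip exactly one digit to a different value."""
    code = list(code)
    i = int(rng.integers(len(code)))
    code[i] = int((code[i] + 1 + rng.integers(n_values - 1)) % n_values)
    return tuple(code)


def make_readout(code, rng, miscall_rate: float = 0.0, n_values: int = 3) -> np.ndarray:
    """One cell's (rounds x channels) intensity matrix: the true value's
    channel is bright (lognormal), the rest background; with probability
    ``miscall_rate`` a round is corrupted — the signal jumps to a wrong
    channel (confident miscall) or is attenuated below the confidence
    ratio (digit left uncalled)."""
    n_digits = len(code)
    out = np.exp(rng.normal(BACKGROUND_LOG_MEAN, BACKGROUND_LOG_SD, (n_digits, n_values)))
    signal = np.exp(rng.normal(SIGNAL_LOG_MEAN, SIGNAL_LOG_SD, n_digits))
    for r, value in enumerate(code):
        target = value
        if miscall_rate and rng.random() < miscall_rate:
            if rng.random() < 2 / 3:   # confident wrong call
                target = int((value + 1 + rng.integers(n_values - 1)) % n_values)
            else:                      # low-confidence round
                signal[r] *= ATTENUATION
        out[r, target] += signal[r]
    return out


def make_readouts(truth: GroundTruth, cell_codes, seed: int = 0) -> list:
    """Readout matrices for the given per-cell true codes."""
    rng = np.random.default_rng(seed)
    return [make_readout(code, rng, truth.miscall_rate) for code in cell_codes]


# ---------------------------------------------------------------------------
# Chromatin traces
# ---------------------------------------------------------------------------

def make_trace_stack(effect: EffectSpec, n_traces: int,
                     profile: CompartmentProfile, rng,
                     tad_dropout: float = 0.0,
                     jitter_sd: float = JITTER_SD_NM) -> np.ndarray:
    """(n_traces, n_tad, 3) positions in nm.

    Baseline: each trace mixes a random-walk backbone with two compartment
    anchor clusters (A targets gather around one anchor, B around the
    other), so polarization and A-A/A-B/B-B contacts are all non-trivial.
    The effect's scale factors then act on the matching geometry: local
    displacements (adjacent), each compartment cluster about its centroid
    (aa/bb), the inter-anchor separation (ab), and the whole trace about
    its centroid (global). Localization jitter and TAD dropout apply last.
    """
    n_tad = profile.n_tad
    labels = profile.label_array()
    is_a = labels == "A"

    u = rng.normal(size=(n_traces, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    anchors_a = u * ANCHOR_SEPARATION_NM / 2
    anchors_b = -anchors_a

    steps = rng.normal(0, RW_STEP_SD_NM * effect.scale_adjacent, (n_traces, n_tad, 3))
    rw = np.cumsum(steps, axis=1)
    rw -= rw.mean(axis=1, keepdims=True)
    local = rng.normal(0, LOCAL_SD_NM * effect.scale_adjacent, (n_traces, n_tad, 3))

    anchor = np.where(is_a[None, :, None], anchors_a[:, None, :], anchors_b[:, None, :])
    pos = anchor + RW_WEIGHT * rw + local

    if effect.scale_aa != 1.0:
        c = pos[:, is_a, :].mean(axis=1, keepdims=True)
        pos[:, is_a, :] = c + (pos[:, is_a, :] - c) * effect.scale_aa
    if effect.scale_bb != 1.0:
        c = pos[:, ~is_a, :].mean(axis=1, keepdims=True)
        pos[:, ~is_a, :] = c + (pos[:, ~is_a, :] - c) * effect.scale_bb
    if effect.scale_ab != 1.0:
        c_all = pos.mean(axis=1, keepdims=True)
        for mask in (is_a, ~is_a):
            c_side = pos[:, mask, :].mean(axis=1, keepdims=True)
            pos[:, mask, :] += (c_side - c_all) * (effect.scale_ab - 1.0)
    if effect.scale_global != 1.0:
        c_all = pos.mean(axis=1, keepdims=True)
        pos = c_all + (pos - c_all) * effect.scale_global

    if jitter_sd:
        pos = pos + rng.normal(0, jitter_sd, pos.shape)
    if tad_dropout:
        drop = rng.random((n_traces, n_tad)) < tad_dropout
        pos[drop] = np.nan
    return pos


def make_traces(truth: GroundTruth, cells_per_sgrna: int,
                profile: CompartmentProfile, seed: int = 0,
                traces_per_cell: tuple = TRACES_PER_CELL):
    """Per-cell traces for every sgRNA in the truth assignment.

    Returns ``(cells, traces_by_sgrna)``: a cell table (cell_id, sgrna,
    code, n_traces) and a dict sgRNA -> (m, n_tad, 3) stack pooling that
    sgRNA's traces across its cells (2-4 chromosome copies per G1 cell).
    """
    rng = np.random.default_rng(seed)
    lo, hi = traces_per_cell
    cells = []
    traces_by_sgrna = {}
    code_of = {sg: code for code, sg in truth.assignment.items()}
    for sg in sorted(set(truth.assignment.values())):
        counts = rng.integers(lo, hi + 1, size=cells_per_sgrna)
        stack = make_trace_stack(
            truth.effect_for(sg), int(counts.sum()), profile, rng,
            tad_dropout=truth.tad_dropout_rate, jitter_sd=truth.jitter_sd_nm,
        )
        traces_by_sgrna[sg] = stack
        for c, n in enumerate(counts):
            cells.append((f"{sg}_cell{c:04d}", sg, code_of[sg], int(n)))
    cell_table = pd.DataFrame(cells, columns=["cell_id", "sgrna", "code", "n_traces"])
    return cell_table, traces_by_sgrna


def traces_to_table(traces_by_sgrna: dict, cell_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format trace table (cell_id, trace_id, tad_index 1-based,
    x_nm, y_nm, z_nm with empty = missing) for on-disk interchange.

    When ``cell_table`` (from :func:`make_traces`) is given, each trace is
    attributed to its generating cell; trace ids are ``<cell_id>_tr<k>``.
    """
    rows = []
    for sg in sorted(traces_by_sgrna):
        stack = traces_by_sgrna[sg]
        if cell_table is not None:
            cells = cell_table[cell_table["sgrna"] == sg]
            cell_ids = np.repeat(cells["cell_id"].to_numpy(),
                                 cells["n_traces"].to_numpy())
            if len(cell_ids) != stack.shape[0]:
                raise ValueError(f"cell table trace counts do not match stack for {sg}")
        else:
            cell_ids = np.array([sg] * stack.shape[0])
        for t in range(stack.shape[0]):
            for k in range(stack.shape[1]):
                x, y, z = stack[t, k]
                rows.append((cell_ids[t], f"{cell_ids[t]}_tr{t:05d}", k + 1,
                             x if np.isfinite(x) else np.nan,
                             y if np.isfinite(y) else np.nan,
                             z if np.isfinite(z) else np.nan))
    return pd.DataFrame(rows, columns=["cell_id", "trace_id", "tad_index", "x_nm", "y_nm", "z_nm"])


# ---------------------------------------------------------------------------
# Nuclear phantoms
# ---------------------------------------------------------------------------

def ellipsoid_mask(semi_axes_nm=NUCLEUS_SEMI_AXES_NM,
                   voxel_size_nm=VOXEL_SIZE_NM,
                   centers_offset_nm=None, pad_vox: int = 2) -> np.ndarray:
    """Binary mask of one ellipsoid, or of a union of two (lobed phantom)
    when ``centers_offset_nm`` gives the +/- center displacement."""
    semi = np.asarray(semi_axes_nm, float)
    vox = np.asarray(voxel_size_nm, float)
    offset = np.zeros(3) if centers_offset_nm is None else np.asarray(centers_offset_nm, float)
    half_extent = semi + np.abs(offset)
    shape = (2 * np.ceil(half_extent / vox)).astype(int) + 1 + 2 * pad_vox
    grids = np.meshgrid(*[(np.arange(s) - (s - 1) / 2) * v for s, v in zip(shape, vox)],
                        indexing="ij")
    coords = np.stack(grids, axis=-1)
    inside = np.zeros(tuple(shape), dtype=bool)
    for sign in (+1.0, -1.0) if centers_offset_nm is not None else (0.0,):
        rel = (coords - sign * offset) / semi
        inside |= (rel ** 2).sum(axis=-1) <= 1.0
    return inside


def make_nucleus(effect: EffectSpec, rng,
                 semi_axes_nm=NUCLEUS_SEMI_AXES_NM,
                 voxel_size_nm=VOXEL_SIZE_NM) -> NucleusImage:
    """One voxelized nuclear phantom under an effect spec.

    ``sphericity_offset < 0`` splits the nucleus into two lobes whose
    separation grows with |offset|; ``condensate_offset`` shifts the count
    of bright condensate blobs controlling intensity unevenness.
    """
    semi = np.asarray(semi_axes_nm, float) * rng.uniform(0.95, 1.05, 3)
    offset_nm = None
    if effect.sphericity_offset < 0:
        sep = min(1.0, -effect.sphericity_offset) * semi[1]
        offset_nm = (0.0, sep, 0.0)
    mask = ellipsoid_mask(semi, voxel_size_nm, offset_nm)

    intensity = np.zeros(mask.shape)
    intensity[mask] = BASE_INTENSITY + rng.normal(0, INTENSITY_NOISE_SD, int(mask.sum()))
    n_blobs = max(0, CONDENSATE_COUNT + effect.condensate_offset)
    if n_blobs:
        zz, yy, xx = np.nonzero(mask)
        picks = rng.integers(len(zz), size=n_blobs)
        grid = np.indices(mask.shape)
        for p in picks:
            d2 = ((grid[0] - zz[p]) ** 2 + (grid[1] - yy[p]) ** 2 + (grid[2] - xx[p]) ** 2)
            intensity += CONDENSATE_AMPLITUDE * np.exp(-d2 / (2 * CONDENSATE_SIGMA_VOX ** 2))
    intensity[~mask] = 0.0
    intensity = np.clip(intensity, 0, None)
    return NucleusImage(intensity=intensity, mask=mask, voxel_size_nm=tuple(voxel_size_nm))


def make_nuclei(effect: EffectSpec, n_cells: int, seed: int = 0, **kwargs) -> list:
    rng = np.random.default_rng(seed)
    return [make_nucleus(effect, rng, **kwargs) for _ in range(n_cells)]


# ---------------------------------------------------------------------------
# Geometric phantoms for closed-form checks
# ---------------------------------------------------------------------------

def sphere_mask(radius_vox: int, pad: int = 2) -> np.ndarray:
    n = 2 * radius_vox + 1 + 2 * pad
    c = (n - 1) / 2
    g = np.indices((n, n, n)) - c
    return (g ** 2).sum(axis=0) <= radius_vox ** 2


def cube_mask(side_vox: int, pad: int = 2) -> np.ndarray:
    out = np.zeros((side_vox + 2 * pad,) * 3, dtype=bool)
    out[pad:pad + side_vox, pad:pad + side_vox, pad:pad + side_vox] = True
    return out


def octahedron_mask(radius_vox: int, pad: int = 2) -> np.ndarray:
    n = 2 * radius_vox + 1 + 2 * pad
    c = (n - 1) / 2
    g = np.abs(np.indices((n, n, n)) - c)
    return g.sum(axis=0) <= radius_vox


def spiked_cube_mask(side_vox: int, spike_len_vox: int, spike_side_vox: int,
                     pad: int = 2) -> np.ndarray:
    """A cube with a thin square spike protruding from one face — a convex
    body strictly less spherical than the plain cube."""
    nz = side_vox + spike_len_vox + 2 * pad
    n = side_vox + 2 * pad
    out = np.zeros((nz, n, n), dtype=bool)
    out[pad:pad + side_vox, pad:pad + side_vox, pad:pad + side_vox] = True
    lo = pad + (side_vox - spike_side_vox) // 2
    out[pad + side_vox:pad + side_vox + spike_len_vox, lo:lo + spike_side_vox,
        lo:lo + spike_side_vox] = True
    return out
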