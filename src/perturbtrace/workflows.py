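"""End-to-end screen workflows built from the library modules.

These are the package's headline computations: the flagship synthetic
screen (decode -> phenotype -> hit calling with planted multi-scale
effects), an all-null calibration of the hit-calling FDR, the
single-miscall decoding-robustness experiment on a minimum-distance-3
codebook, and the library-dropout QC round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codebook as cb
from .barcode import Codebook, code_from_string, decode_readout, ternary_min_distance_codes, code_to_string
from .nucleus import nuclear_features, nuclear_tests
from .screen import EFFECT_FLOOR, FDR_THRESHOLD, call_hits, phenotype_table
from .synthetic import (
    EffectSpec,
    GroundTruth,
    default_compartment_profile,
    make_library,
    make_nuclei,
    make_read_tables,
    make_readouts,
    make_traces,
)
from .traces import CompartmentProfile


# ---------------------------------------------------------------------------
# Flagship synthetic screen
# ---------------------------------------------------------------------------

DEFAULT_PLANTED = {
    # two compactors, two decompactors, one sphericity-down, one unevenness-down
    "sgGENE001_1": EffectSpec(scale_global=0.8),
    "sgGENE002_1": EffectSpec(scale_global=0.8),
    "sgGENE003_1": EffectSpec(scale_global=1.25),
    "sgGENE004_1": EffectSpec(scale_global=1.25),
    "sgGENE005_1": EffectSpec(sphericity_offset=-0.45),
    "sgGENE006_1": EffectSpec(condensate_offset=-5),
}

CHROMATIN_DIRECTION = {  # expected log2fc sign per phenotype for a compactor
    "adjacent_tad": -1, "overall_distance": -1,
    "freq_AA": +1, "freq_AB": +1, "freq_BB": +1,
}


@dataclass
class ScreenResult:
    phenotypes: pd.DataFrame
    hits: pd.DataFrame
    truth: GroundTruth
    decode_stats: dict
    planted: dict = field(default_factory=dict)

    def hit_sgrnas(self) -> set:
        return set(self.hits["sgrna"])


def _expected_direction(effect: EffectSpec, phenotype: str) -> int:
    """Sign of the planted effect on a phenotype (0 = no expectation)."""
    if phenotype == "sphericity":
        return int(np.sign(effect.sphericity_offset))
    if phenotype == "intensity_cov":
        return int(np.sign(effect.condensate_offset))
    if effect.scale_global != 1.0 and phenotype in CHROMATIN_DIRECTION:
        # CHROMATIN_DIRECTION is tabulated for a compactor (scale < 1)
        return -int(np.sign(effect.scale_global - 1.0)) * CHROMATIN_DIRECTION[phenotype]
    return 0


def run_synthetic_screen(seed: int = 0, n_sgrnas: int = 60, n_controls: int = 10,
                         cells_per_sgrna: int = 120, nuclei_per_sgrna: int = 25,
                         planted: dict | None = None,
                         miscall_rate: float = 0.02,
                         tad_dropout_rate: float = 0.03,
                         with_nuclei: bool = True,
                         profile: CompartmentProfile | None = None,
                         fdr_threshold: float = FDR_THRESHOLD,
                         effect_floor: float = EFFECT_FLOOR) -> ScreenResult:
    """Generate a synthetic screen, decode every cell's barcode readout,
    pool decoded traces per sgRNA, and call hits against the pooled
    non-targeting controls."""
    planted = DEFAULT_PLANTED if planted is None else planted
    n_targeting = n_sgrnas - n_controls
    n_genes = n_targeting // 2 if n_targeting % 2 == 0 else (n_targeting + 1) // 2
    if not 2 * n_genes <= n_targeting <= 3 * n_genes:
        n_genes = (n_targeting + 2) // 3
    library, truth = make_library(
        n_targeting=n_targeting, n_controls=n_controls, n_genes=n_genes, seed=seed,
    )
    truth.effects = {sg: eff for sg, eff in planted.items()
                     if sg in set(library["sgrna_id"])}
    if len(truth.effects) != len(planted):
        missing = set(planted) - set(truth.effects)
        raise ValueError(f"planted sgRNAs absent from library: {sorted(missing)}")
    truth.miscall_rate = miscall_rate
    truth.tad_dropout_rate = tad_dropout_rate
    profile = profile or default_compartment_profile()

    cell_table, traces_by_true_sgrna = make_traces(
        truth, cells_per_sgrna, profile, seed=seed + 1,
    )

    # BARC-FISH decoding of every cell
    codes = [code_from_string(c) for c in cell_table["code"]]
    readouts = make_readouts(truth, codes, seed=seed + 2)
    statuses = []
    decoded = []
    for ro in readouts:
        res = decode_readout(ro, truth.codebook)
        statuses.append(res.status)
        decoded.append(res.sgrna)
    cell_table = cell_table.assign(decoded_sgrna=decoded, decode_status=statuses)
    decode_stats = {
        "n_cells": len(cell_table),
        "assigned_fraction": float((cell_table["decode_status"] == "assigned").mean()),
        "correct_fraction": float(
            (cell_table["decoded_sgrna"] == cell_table["sgrna"]).mean()
        ),
        "status_counts": cell_table["decode_status"].value_counts().to_dict(),
    }

    # Pool traces by DECODED identity, as the real pipeline must.
    traces_by_sgrna = {}
    cursor = {sg: 0 for sg in traces_by_true_sgrna}
    chunks: dict = {}
    for row in cell_table.itertuples():
        sg_true = row.sgrna
        n = row.n_traces
        start = cursor[sg_true]
        cursor[sg_true] = start + n
        if row.decode_status != "assigned":
            continue
        chunks.setdefault(row.decoded_sgrna, []).append(
            traces_by_true_sgrna[sg_true][start:start + n]
        )
    for sg, parts in chunks.items():
        traces_by_sgrna[sg] = np.concatenate(parts, axis=0)

    controls = library.loc[library["is_control"], "sgrna_id"].tolist()
    table = phenotype_table(traces_by_sgrna, controls, profile)

    if with_nuclei:
        feats = {}
        for k, sg in enumerate(sorted(library["sgrna_id"])):
            nuclei = make_nuclei(truth.effect_for(sg), nuclei_per_sgrna,
                                 seed=seed + 10_000 + k)
            rows = [nuclear_features(nuc) for nuc in nuclei]
            feats[sg] = {
                "sphericity": np.array([r["sphericity"] for r in rows]),
                "cov": np.array([r["cov"] for r in rows]),
            }
        nuc_table = nuclear_tests(feats, controls)
        nuc_table = nuc_table.rename(columns={"n_cells": "n_traces"})
        table = pd.concat([table, nuc_table], ignore_index=True)

    hits = call_hits(table, fdr_threshold=fdr_threshold, effect_floor=effect_floor)
    return ScreenResult(table, hits, truth, decode_stats, planted=dict(truth.effects))


def score_recovery(result: ScreenResult) -> dict:
    """Compare called hits with the planted truth.

    A planted effect is recovered when the sgRNA is a hit in at least one
    phenotype it truly moves, with the correct direction; a false positive
    is any non-planted sgRNA called in any phenotype.
    """
    planted = result.planted
    hits = result.hits
    recovered, wrong_direction = [], []
    for sg, eff in planted.items():
        sub = hits[hits["sgrna"] == sg]
        ok = False
        for row in sub.itertuples():
            exp = _expected_direction(eff, row.phenotype)
            if exp != 0 and np.sign(row.log2fc) == exp:
                ok = True
            elif exp != 0 and np.sign(row.log2fc) == -exp:
                wrong_direction.append((sg, row.phenotype))
        if ok:
            recovered.append(sg)
    false_sgrnas = sorted(set(hits["sgrna"]) - set(planted))
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "recovered": sorted(recovered),
        "wrong_direction": wrong_direction,
        "false_positive_sgrnas": false_sgrnas,
        "n_false_positives": len(false_sgrnas),
    }


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def null_calibration(seed: int = 0, n_reps: int = 20, n_sgrnas: int = 20,
                     n_controls: int = 5, cells_per_sgrna: int = 60,
                     fdr_threshold: float = FDR_THRESHOLD) -> dict:
    """All-null screens: every sgRNA drawn from the control distribution.

    Returns the fraction of (perturbation, phenotype) tests called at the
    FDR threshold (with the effect floor) across replicates — the empirical
    false-hit rate, which Benjamini-Hochberg should keep at or below the
    nominal level.
    """
    n_called = 0
    n_tests = 0
    per_rep = []
    for rep in range(n_reps):
        res = run_synthetic_screen(
            seed=seed + 7919 * (rep + 1), n_sgrnas=n_sgrnas, n_controls=n_controls,
            cells_per_sgrna=cells_per_sgrna, planted={}, with_nuclei=False,
            fdr_threshold=fdr_threshold,
        )
        tested = res.phenotypes[~res.phenotypes["is_control"] & res.phenotypes["fdr"].notna()]
        per_rep.append(len(res.hits) / len(tested) if len(tested) else 0.0)
        n_called += len(res.hits)
        n_tests += len(tested)
    return {
        "false_hit_fraction": n_called / n_tests if n_tests else 0.0,
        "n_called": n_called,
        "n_tests": n_tests,
        "per_rep": per_rep,
    }


# ---------------------------------------------------------------------------
# Decoding robustness
# ---------------------------------------------------------------------------

def decode_robustness_experiment(seed: int = 0, n_codes: int = 420,
                                 cells_per_code: int = 2,
                                 max_correction: int = 1) -> dict:
    """One corrupted trit per cell against a codebook with guaranteed
    minimum pairwise trit distance 3: radius-1 correction must recover
    every cell."""
    rng = np.random.default_rng(seed)
    codes = ternary_min_distance_codes(n_codes, seed=seed)
    codebook = Codebook(good={code_to_string(c): f"sg{k:04d}" for k, c in enumerate(codes)})
    n_correct = 0
    n_cells = 0
    from .barcode import decode
    from .synthetic import corrupt_one_trit

    for k, code in enumerate(codes):
        for _ in range(cells_per_code):
            corrupted = corrupt_one_trit(code, rng)
            res = decode(corrupted, codebook, max_correction=max_correction)
            n_cells += 1
            if res.assigned and res.sgrna == f"sg{k:04d}" and res.corrected_digits == 1:
                n_correct += 1
    return {
        "n_cells": n_cells,
        "n_correct": n_correct,
        "recovery_pct": 100.0 * n_correct / n_cells,
    }


# ---------------------------------------------------------------------------
# Library dropout QC round trip
# ---------------------------------------------------------------------------

def dropout_qc_experiment(seed: int = 0, n_dropout: int = 8,
                          umis_per_pair: int = 8) -> dict:
    """Full-design library (420 sgRNAs) with ``n_dropout`` sgRNAs lost in
    construction, pushed through the UMI join and good/bad classification;
    reports the recovered dropout percentage (the full design with 8 lost
    sgRNAs gives 1.9%)."""
    library, truth = make_library(seed=seed, planted_dropout=n_dropout)
    sg_reads, bc_reads = make_read_tables(truth, umis_per_pair=umis_per_pair, seed=seed + 1)
    pairs = cb.join_by_umi(sg_reads, bc_reads)
    built = cb.classify_codes(pairs, min_reads=2)
    qc = cb.library_qc(built, library)
    return {
        "n_designed": qc.n_designed,
        "n_detected": qc.n_detected,
        "dropout_pct": qc.dropout_pct,
        "n_good_codes": qc.n_good_codes,
        "n_bad_codes": qc.n_bad_codes,
    }
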