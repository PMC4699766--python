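"""End-to-end replication: simulate, gate, describe, compare, invert.

``run_replication`` chains the whole analysis on synthetic data: generate
the multi-dose study, auto-gate each dose group down to isolated G0/G1
nuclei, compute the observed-count statistics table, build the matching
specific-energy statistics table for the three target volumes (whole nucleus,
DNA molecule, matched volume) with the same per-dose sample sizes, run the
Q-Q comparisons, and invert the fitted SD_rel(V, D) relation on the observed
relative SDs to recover the matched target volume.  Everything is seeded
from one root seed, so a fixed seed yields a byte-identical report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .energy import (
    CalibrationResult,
    energy_distribution,
    invert_target_volume,
    sample_specific_energy,
)
from .gating import apply_gate, auto_gate_thresholds
from .popstats import describe_counts, fit_dose_response, fold_change_series, qq_compare, tail_metrics
from .population import DEFAULT_DOSE_GROUPS, PopulationConfig, simulate_study
from .reference import (
    DNA_VOLUME_UM3,
    MATCHED_VOLUME_UM3,
    NUCLEUS_VOLUME_UM3,
    default_cobalt60_calibration,
)

__all__ = ["run_replication"]

DEFAULT_QQ_VOLUMES = (NUCLEUS_VOLUME_UM3, DNA_VOLUME_UM3, MATCHED_VOLUME_UM3)


def _describe_energy(sample: np.ndarray) -> dict:
    s = describe_counts(sample)
    return {
        "n": s.n,
        "mean": s.mean,
        "median": s.median,
        "var": s.var,
        "sd": s.sd,
        "sd_rel": s.sd_rel,
    }


def run_replication(
    seed: int = 0,
    dose_groups: dict[float, tuple[int, int]] | None = None,
    config: PopulationConfig | None = None,
    calibration: CalibrationResult | None = None,
    volumes: tuple[float, ...] = DEFAULT_QQ_VOLUMES,
    return_tables: bool = False,
):
    """Run the full pipeline and return a JSON-serializable report.

    Parameters
    ----------
    seed : int
        Root seed for the generator and all energy sampling.
    dose_groups : mapping dose -> (pooled n, replicates), optional
    config : PopulationConfig template, optional
    calibration : CalibrationResult, optional
        Beam calibration; defaults to the Co-60 reference fit.
    volumes : target volumes (um^3) for the energy table and Q-Q plots.
    return_tables : bool
        If True, also return the simulated and gated per-nucleus tables.
    """
    if dose_groups is None:
        dose_groups = DEFAULT_DOSE_GROUPS
    if calibration is None:
        calibration = default_cobalt60_calibration()
    model = calibration.model

    study = simulate_study(dose_groups=dose_groups, seed=seed, model=model, config=config)

    doses = sorted(dose_groups)
    irradiated = [d for d in doses if d > 0]

    # gate each dose group with gates derived from that group's own scatter
    gated_frames = []
    gate_provenance = {}
    for dose in doses:
        grp = study[study["dose_nominal_Gy"] == dose]
        morpho, intensity = auto_gate_thresholds(grp)
        result = apply_gate(grp, morpho, intensity)
        gated_frames.append(grp.loc[result.selected])
        gate_provenance[f"{dose:g}"] = {
            "morphology_gate": morpho.to_dict(),
            "intensity_gate": intensity.to_dict(),
            **result.to_dict(),
        }
    gated = pd.concat(gated_frames, ignore_index=True)

    # observed-count statistics per dose (the Table-1 analogue)
    counts_stats = {}
    for dose in doses:
        counts = gated.loc[gated["dose_nominal_Gy"] == dose, "rif_count"].to_numpy()
        counts_stats[f"{dose:g}"] = describe_counts(counts).to_dict()
    irr_stats = [(d, describe_counts(
        gated.loc[gated["dose_nominal_Gy"] == d, "rif_count"].to_numpy()
    )) for d in irradiated]
    fold_sd_rel = fold_change_series(irr_stats, "sd_rel")
    fold_sd = fold_change_series(irr_stats, "sd")

    # dose response over replicate means (gated data)
    replicate_means = {
        float(d): gated[gated["dose_nominal_Gy"] == d]
        .groupby("replicate_id")["rif_count"]
        .mean()
        .tolist()
        for d in doses
    }
    dose_fit = fit_dose_response(replicate_means)

    # specific-energy statistics for each volume at each irradiated dose,
    # with the same number of synthetic events as gated nuclei
    energy_root = np.random.SeedSequence((seed, 10_001))
    energy_streams = iter(energy_root.spawn(len(volumes) * len(irradiated) * 2))
    energy_stats: dict[str, dict] = {}
    qq: dict[str, dict] = {}
    for vol in volumes:
        vol_stats = {}
        vol_qq = {}
        for dose in irradiated:
            counts = gated.loc[gated["dose_nominal_Gy"] == dose, "rif_count"].to_numpy()
            spec = energy_distribution(model, vol, dose)
            z = sample_specific_energy(spec, counts.size, np.random.default_rng(next(energy_streams)))
            vol_stats[f"{dose:g}"] = _describe_energy(z)
            res = qq_compare(counts, z)
            vol_qq[f"{dose:g}"] = {
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.r_squared,
            }
        vol_stats["fold_change_sd_rel"] = [
            vol_stats[f"{b:g}"]["sd_rel"] / vol_stats[f"{a:g}"]["sd_rel"]
            for a, b in zip(irradiated, irradiated[1:])
        ]
        energy_stats[f"{vol:g}"] = vol_stats
        qq[f"{vol:g}"] = vol_qq

    # invert the energy-spread relation on the observed relative SDs
    inverted = {
        f"{d:g}": invert_target_volume(model, counts_stats[f"{d:g}"]["sd_rel"], d)
        for d in irradiated
    }
    inverted_mean = float(np.mean(list(inverted.values())))

    # low tail of the highest dose against the next-lower dose's mean
    tails = {}
    if len(irradiated) >= 2:
        top, ref = irradiated[-1], irradiated[-2]
        top_counts = gated.loc[gated["dose_nominal_Gy"] == top, "rif_count"].to_numpy()
        ref_mean = counts_stats[f"{ref:g}"]["mean"]
        tm = tail_metrics(top_counts, ref_mean, percentiles=(15.0,))
        tails = {
            "dose_Gy": top,
            "reference_dose_Gy": ref,
            "reference_mean": ref_mean,
            **tm.to_dict(),
        }

    report = {
        "seed": seed,
        "calibration": calibration.to_dict(),
        "dose_groups": {f"{d:g}": list(dose_groups[d]) for d in doses},
        "gates": gate_provenance,
        "observed_counts": counts_stats,
        "fold_change_sd_rel": fold_sd_rel,
        "fold_change_sd": fold_sd,
        "dose_response": dose_fit.to_dict(),
        "specific_energy": energy_stats,
        "qq": qq,
        "inverted_volume_um3": inverted,
        "inverted_volume_mean_um3": inverted_mean,
        "tail": tails,
    }
    if return_tables:
        return report, study, gated
    return report
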