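"""End-to-end pipeline: synthetic generation -> fitting -> reporting.

Each ``cmd_*`` function is the library form of one CLI command; all of
them take a :class:`~gelnmr.io.PipelineConfig`, never mutate their input
files, and are reproducible given the configured seed.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    PipelineConfig,
    config_hash,
    read_curve_csv,
    read_profile_csv,
    write_curve_csv,
    write_json,
    write_profile_csv,
)
from .nmrd_fit import (
    FitProtocol,
    derive_quantities,
    fit_nmrd_joint,
    low_frequency_discriminant,
)
from .quality import COLOR_TABLE, TPA_TABLE, delta_e, relative_change, tpa_derived
from .synth import (
    SAMPLE_MOISTURE_PCT,
    SAMPLE_T2_PARAMS,
    AcquisitionSpec,
    make_frequency_grid,
    nmrd_params_for,
    simulate_cpmg_decay,
    simulate_nmrd_profile,
)
from .tdnmr import fit_discrete_multiexp, ilt_t2_spectrum, spectrum_peaks

__all__ = ["cmd_simulate", "cmd_fit", "cmd_t2", "cmd_quality", "cmd_report"]

log = logging.getLogger(__name__)


def _child_seed(base_seed: int, *key) -> int:
    # stable across processes (unlike built-in str hashing)
    digest = hashlib.sha256(repr(key).encode()).digest()
    entropy = [int(base_seed), int.from_bytes(digest[:4], "little")]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def _profile_path(outdir: Path, sample: str, temp: float) -> Path:
    return outdir / f"profile_{sample}_{temp:g}C.csv"


def _cpmg_path(outdir: Path, sample: str) -> Path:
    return outdir / f"cpmg_{sample}.csv"


def cmd_simulate(config: PipelineConfig) -> dict:
    """Write NMRD profiles, CPMG decays and ground-truth sidecars per sample."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    grid = make_frequency_grid(
        config.f_min_hz, config.f_max_hz, config.n_frequencies,
        config.extra_frequencies_hz,
    )
    manifest = {"version": __version__, "config_sha": chash, "seed": config.seed,
                "files": []}
    for sample in config.samples:
        for temp in config.temperatures:
            params = nmrd_params_for(sample, temp)  # raises listing fixtures
            seed = _child_seed(config.seed, "nmrd", sample, temp)
            profile = simulate_nmrd_profile(
                params, grid, noise_fraction=config.noise_fraction, seed=seed,
                sample_id=sample, temperature_C=temp,
            )
            path = _profile_path(outdir, sample, temp)
            write_profile_csv(profile, path, {"seed": seed, "config_sha": chash})
            write_json(path.with_suffix(".truth.json"),
                       {"params": params.to_flat_dict(), "seed": seed,
                        "noise_fraction": config.noise_fraction})
            manifest["files"].append(path.name)
        spec = AcquisitionSpec(
            sequence="CPMG", echo_time=config.cpmg_echo_time_s,
            n_echoes=config.cpmg_n_echoes,
        )
        seed = _child_seed(config.seed, "cpmg", sample)
        decay = simulate_cpmg_decay(
            SAMPLE_T2_PARAMS[sample], spec, noise_sd=config.cpmg_noise_sd, seed=seed
        )
        path = _cpmg_path(outdir, sample)
        write_curve_csv(decay, path, {"sample": sample, "seed": seed,
                                      "config_sha": chash})
        write_json(path.with_suffix(".truth.json"), decay.truth | {"sample": sample})
        manifest["files"].append(path.name)
        log.info("simulated %s: %d profiles + CPMG decay", sample,
                 len(config.temperatures))
    write_json(outdir / "manifest.json", manifest)
    return manifest


def _protocol_from_config(config: PipelineConfig) -> FitProtocol:
    window = (
        tuple(config.downweight_window_hz) if config.downweight_window_hz else None
    )
    return FitProtocol(
        n_multistart=config.n_multistart,
        seed=_child_seed(config.seed, "fit"),
        downweight_window=window,
    )


def cmd_fit(config: PipelineConfig) -> dict:
    """Joint NMRD fits per sample, derived spin-density table, discriminant."""
    outdir = Path(config.outdir)
    chash = config_hash(config)
    protocol = _protocol_from_config(config)
    results, errors = {}, {}
    ref_temp = protocol.reference_temperature_C
    for sample in config.samples:
        ref_path = _profile_path(outdir, sample, ref_temp)
        if not ref_path.exists():
            errors[sample] = f"missing reference-temperature profile {ref_path.name}"
            continue
        profile_ref = read_profile_csv(ref_path)
        profile_low = None
        low_temps = [t for t in config.temperatures if t != ref_temp]
        if low_temps:
            low_path = _profile_path(outdir, sample, low_temps[0])
            if low_path.exists():
                profile_low = read_profile_csv(low_path)
            else:
                log.warning(
                    "%s: no %g C profile; running reference-temperature fit only",
                    sample, low_temps[0],
                )
        try:
            results[sample] = fit_nmrd_joint(profile_ref, profile_low, protocol)
        except Exception as exc:
            log.error("fit failed for %s: %s", sample, exc)
            errors[sample] = str(exc)
    # derived quantities against the reference sample
    reference = results.get(config.reference)
    rows, report = [], {}
    for sample, res in results.items():
        derived = derive_quantities(
            res,
            reference=reference,
            moisture_pct=SAMPLE_MOISTURE_PCT.get(sample),
            reference_moisture_pct=SAMPLE_MOISTURE_PCT.get(config.reference),
        )
        report[sample] = {
            "parameters": res.params_report(),
            "derived": derived.report(),
            "cost": res.cost,
            "messages": res.messages,
        }
        for temp, p in res.params_by_temperature.items():
            rows.append({
                "sample": sample,
                "temperature_C": temp,
                "C_intra_1e9_per_s2": p.rot.C_intra / 1e9,
                "tau_rot_ns": p.rot.tau_rot / 1e-9,
                "D_mm_1e-12_m2s": p.mm.D / 1e-12,
                "D_lm_1e-13_m2s": p.lm.D / 1e-13,
                "N_mm_1e28_per_m3": res.N_mm / 1e28,
                "N_lm_1e28_per_m3": res.N_lm / 1e28,
                "N_total_1e28_per_m3": derived.report()["N_total_1e28_per_m3"],
                "relative_change_N": derived.report()["relative_change_N"],
                "ratio_N_mm_over_N_lm": derived.report()["ratio_N_mm_over_N_lm"],
                "moisture_pct": SAMPLE_MOISTURE_PCT.get(sample),
                "relative_change_moisture": derived.report()["relative_change_moisture"],
            })
    summary = pd.DataFrame(rows)
    summary_path = outdir / "nmrd_summary.csv"
    with open(summary_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# gelnmr_version={__version__}\n# config_sha={chash}\n"
                 f"# seed={config.seed}\n")
        summary.to_csv(fh, index=False, lineterminator="\n")
    # low-frequency discrimination per temperature
    discriminants = {}
    for temp in config.temperatures:
        profiles = [
            read_profile_csv(_profile_path(outdir, s, temp))
            for s in config.samples
            if _profile_path(outdir, s, temp).exists()
        ]
        if len(profiles) >= 2:
            disc = low_frequency_discriminant(profiles)
            discriminants[str(temp)] = {
                "statistic_per_s": disc.statistic,
                "ranking": disc.ranking,
                "original_like": disc.original_like,
                "tie": disc.tie,
                "cutoff_hz": disc.cutoff_hz,
            }
    payload = {
        "version": __version__, "config_sha": chash, "seed": config.seed,
        "samples": report, "errors": errors, "discriminant": discriminants,
    }
    write_json(outdir / "fit_report.json", payload)
    return payload


def cmd_t2(config: PipelineConfig) -> dict:
    """Discrete T2 decomposition + regularized spectrum + peak table per sample."""
    outdir = Path(config.outdir)
    chash = config_hash(config)
    rows, report = [], {}
    for sample in config.samples:
        path = _cpmg_path(outdir, sample)
        if not path.exists():
            report[sample] = {"error": f"missing decay {path.name}"}
            continue
        decay = read_curve_csv(path)
        discrete = fit_discrete_multiexp(decay, config.n_t2_components)
        spectrum = ilt_t2_spectrum(
            decay, regularization_strength=config.ilt_regularization
        )
        peaks = spectrum_peaks(spectrum)
        spec_df = pd.DataFrame(
            {"T2_ms": spectrum.grid * 1e3, "amplitude": spectrum.amplitudes}
        )
        spec_path = outdir / f"spectrum_{sample}.csv"
        with open(spec_path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# gelnmr_version={__version__}\n# sample={sample}\n"
                     f"# config_sha={chash}\n# seed={config.seed}\n"
                     f"# regularization={config.ilt_regularization}\n")
            spec_df.to_csv(fh, index=False, lineterminator="\n")
        report[sample] = {
            "discrete": discrete.report(),
            "spectrum_peaks": peaks.report(),
        }
        rows.append({"sample": sample, **discrete.report()})
    summary = pd.DataFrame(rows)
    with open(outdir / "t2_summary.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# gelnmr_version={__version__}\n# config_sha={chash}\n"
                 f"# seed={config.seed}\n")
        summary.to_csv(fh, index=False, lineterminator="\n")
    payload = {"version": __version__, "config_sha": chash, "seed": config.seed,
               "samples": report}
    write_json(outdir / "t2_report.json", payload)
    return payload


def cmd_quality(config: PipelineConfig) -> dict:
    """Color-change, TPA product and moisture-change metrics table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    if config.quality_input:
        df = pd.read_csv(config.quality_input, comment="#").set_index("sample")
    else:
        df = pd.DataFrame(
            {
                "L": {s: c.L for s, c in COLOR_TABLE.items()},
                "a": {s: c.a for s, c in COLOR_TABLE.items()},
                "b": {s: c.b for s, c in COLOR_TABLE.items()},
                "hardness_N": {s: t.hardness for s, t in TPA_TABLE.items()},
                "cohesiveness": {s: t.cohesiveness for s, t in TPA_TABLE.items()},
                "springiness_mm": {s: t.springiness for s, t in TPA_TABLE.items()},
                "moisture_pct": SAMPLE_MOISTURE_PCT,
            }
        )
        df.index.name = "sample"
    ref = config.reference
    if ref not in df.index:
        raise ValueError(f"reference sample {ref!r} not in quality table")
    from .quality import ColorLab  # local import to keep module surface tidy

    ref_color = ColorLab(df.loc[ref, "L"], df.loc[ref, "a"], df.loc[ref, "b"])
    rows = []
    for sample, r in df.iterrows():
        gum, chew = tpa_derived(r["hardness_N"], r["cohesiveness"], r["springiness_mm"])
        rows.append({
            "sample": sample,
            "delta_e_vs_" + ref: delta_e(ColorLab(r["L"], r["a"], r["b"]), ref_color),
            "gumminess_N": gum,
            "chewiness_N_mm": chew,
            "moisture_relative_change": relative_change(
                r["moisture_pct"], df.loc[ref, "moisture_pct"]
            ),
        })
    out = pd.DataFrame(rows)
    with open(outdir / "quality_metrics.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# gelnmr_version={__version__}\n# config_sha={chash}\n"
                 f"# seed={config.seed}\n# reference={ref}\n")
        out.to_csv(fh, index=False, lineterminator="\n")
    return {"rows": rows, "reference": ref}


def cmd_report(config: PipelineConfig) -> dict:
    """Full chain: simulate, fit, T2 analysis, quality metrics."""
    manifest = cmd_simulate(config)
    fit = cmd_fit(config)
    t2 = cmd_t2(config)
    quality = cmd_quality(config)
    return {"manifest": manifest, "fit": fit, "t2": t2, "quality": quality}
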