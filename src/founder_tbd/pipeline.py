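"""End-to-end orchestration: simulate -> haplotype -> screen -> segregate
-> assay -> telomere, with a consolidated, seed-deterministic report.

The pipeline runs on simulator output so a complete founder-variant
analysis can be reproduced from a single seed: it delimits the shared
block among simulated carriers, distills the rare in-cis markers,
screens phased and unphased control panels for the founder haplotype,
tests co-segregation in simulated families, quantifies simulated
direct-assay lanes, and scores shifted carrier telomere lengths against
a control reference.  Every threshold that shapes the conclusions (MAF
cutoff, fit window, age window, percentile threshold) is logged into the
report's provenance; identical config and seed give byte-identical
report JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .control_screen import phased_haplotype_screen, unphased_control_screen
from .haplotype_core import (
    MarkerSet,
    carrier_haplotypes,
    filter_rare_snvs,
    interval_span,
    shared_block,
)
from .segregation import cosegregation_check
from .synthetic_data import (
    AssayParams,
    SimConfig,
    TLRefParams,
    drop_phase,
    simulate_control_panel,
    simulate_families,
    simulate_founder_population,
    simulate_gel_lane,
    simulate_tl_cases,
    simulate_tl_reference,
)
from .telomerase_quant import compare_variants, estimate_processivity
from .telomere_percentiles import build_reference, flag_below

ALL_STAGES = ("simulate", "haplotype", "screen", "segregate", "assay", "telomere")


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    seed: int = 0
    out_dir: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    maf_threshold: float = 0.01
    control_haplotypes: int = 2000
    # direct-assay study conditions: WT mean processivity 4 repeats;
    # variant at 0.67x processivity and 0.76x activity of WT
    wt_dissociation: float = 0.25
    variant_processivity_ratio: float = 0.67
    variant_activity_ratio: float = 0.76
    assay_replicates: int = 3
    assay_noise_sd: float = 0.05
    tl: dict = field(default_factory=dict)  # TLRefParams overrides
    tl_cases: int = 50
    tl_shift_sd: float = -2.0
    tl_threshold: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages enabled")
        need = {"haplotype": "simulate", "screen": "haplotype", "segregate": "simulate"}
        for stage, dep in need.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(f"stage '{stage}' requires stage '{dep}'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "out_dir" in raw and raw["out_dir"] is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
        return d


@dataclass
class ReportBundle:
    """Consolidated pipeline report; serializes to deterministic JSON."""

    block: dict | None
    screen: dict | None
    segregation: list[dict] | None
    assay: dict | None
    telomere: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


class StageError(RuntimeError):
    """A pipeline stage failed; the stage is named in the message."""


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in dependency order.

    Stage failures abort the run with the failing stage named; outputs of
    completed stages are already on disk (when ``out_dir`` is set) for
    debugging.
    """
    out = config.out_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
    # independent child streams per stage, all derived from the one seed
    seeds = np.random.SeedSequence(config.seed).spawn(len(ALL_STAGES))
    rngs = {name: np.random.default_rng(s) for name, s in zip(ALL_STAGES, seeds)}

    panel = truth = None
    markers: MarkerSet | None = None
    block_report = screen_report = assay_report = telomere_report = None
    seg_reports = None
    sim_config = SimConfig(**{"seed": config.seed, **config.sim})

    def stage(name: str) -> bool:
        return name in config.stages

    try:
        name = "simulate"
        if stage(name):
            panel, truth = simulate_founder_population(sim_config, rngs[name])
            if out is not None:
                from .io import write_truth_json, write_vcf

                write_vcf(panel, out / "carriers_phased.vcf")
                write_vcf(drop_phase(panel), out / "carriers_unphased.vcf")
                write_truth_json(truth, out / "truth.json")

        name = "haplotype"
        if stage(name):
            target = panel.sites[sim_config.target_index]
            carriers = carrier_haplotypes(panel, target)
            block = shared_block(carriers, panel.sites)
            markers = filter_rare_snvs(block, panel.sites, threshold=config.maf_threshold)
            block_report = {
                "chrom": block.chrom,
                "start": block.start,
                "end": block.end,
                "span_bp": interval_span(block.start, block.end),
                "n_carrier_haplotypes": block.n_carriers,
                "n_markers": len(markers.markers),
                "marker_positions": [m.pos for m in markers.markers],
                "flanks_defined": markers.flanks_defined,
            }
            if out is not None:
                from .io import write_markers_json

                write_markers_json(markers, block, out / "block.json")

        name = "screen"
        if stage(name):
            rng = rngs[name]
            controls = simulate_control_panel(panel.sites, config.control_haplotypes, rng)
            phased = phased_haplotype_screen(controls, markers)
            unphased = unphased_control_screen(drop_phase(controls), markers)
            carriers_screen = unphased_control_screen(
                drop_phase(panel), markers, require_no_target_alt=False
            )
            carrier_ids = {s for s, _ in truth.carriers}
            carrier_calls = [c for c in carriers_screen.calls if c.sample in carrier_ids]
            screen_report = {
                "phased_controls": {
                    "n_haplotypes": phased.n_screened,
                    "full_haplotype_hits": phased.phased_haplotype_hits,
                    "partial_haplotype_hits": phased.n_partial_only,
                },
                "unphased_controls": {
                    "n_screened": unphased.n_screened,
                    "n_full": unphased.n_full,
                    "n_partial_only": unphased.n_partial_only,
                },
                "carriers": {
                    "n_carriers": len(carrier_calls),
                    "n_full": sum(c.cls == "full" for c in carrier_calls),
                    "n_partial_only": sum(c.cls == "partial" for c in carrier_calls),
                },
            }

        name = "segregate"
        if stage(name):
            rng = rngs[name]
            peds, fams, founder_strs, fam_sites = simulate_families(sim_config, rng)
            fam_markers = _markers_from_truth(sim_config, fam_sites)
            seg_reports = []
            for ped, fam in zip(peds, fams):
                rep = cosegregation_check(
                    fam, ped, fam_markers, founder_str_alleles={"D5S1981": founder_strs["D5S1981"]}
                )
                seg_reports.append(
                    {
                        "family": ped.fid,
                        "cosegregates": rep.cosegregates,
                        "n_informative_meioses": rep.n_informative_meioses,
                        "mendelian_errors": rep.mendelian_errors,
                        "notes": rep.notes,
                    }
                )
            if out is not None:
                from .io import write_microsat_tsv, write_ped

                write_ped(peds, out / "families.ped")
                write_microsat_tsv(fams, [p.fid for p in peds], out / "microsatellites.tsv")

        name = "assay"
        if stage(name):
            rng = rngs[name]
            wt_d = config.wt_dissociation
            var_proc = config.variant_processivity_ratio / wt_d
            var_d = 1.0 / var_proc
            # Total lane signal scales as activity_scale / d (mean product
            # length is 1/d), so the pre-factor is compensated to make the
            # true total-signal (activity) ratio equal the configured one.
            groups = {
                "WT": AssayParams(dissociation_prob=wt_d, noise_sd=config.assay_noise_sd),
                "variant": AssayParams(
                    dissociation_prob=var_d,
                    activity_scale=1000.0 * config.variant_activity_ratio * (var_d / wt_d),
                    noise_sd=config.assay_noise_sd,
                ),
            }
            activity: dict[str, list[float]] = {}
            processivity: dict[str, list[float]] = {}
            for label, params in groups.items():
                activity[label] = []
                processivity[label] = []
                for _ in range(config.assay_replicates):
                    lane = simulate_gel_lane(params, rng, label=label)
                    activity[label].append(
                        (float(lane.intensities.sum()) / lane.lc) / lane.ip_htr
                    )
                    processivity[label].append(
                        estimate_processivity(lane).processivity
                    )
            act_cmp = compare_variants(activity["variant"], activity["WT"], "variant")
            proc_cmp = compare_variants(processivity["variant"], processivity["WT"], "variant")
            assay_report = {
                "activity": _cmp_dict(act_cmp),
                "processivity": _cmp_dict(proc_cmp),
                "wt_mean_processivity": float(np.mean(processivity["WT"])),
            }

        name = "telomere"
        if stage(name):
            rng = rngs[name]
            tl_params = TLRefParams(**{"seed": config.seed, **config.tl})
            controls = simulate_tl_reference(tl_params, rng)
            ref = build_reference(controls)
            cases = simulate_tl_cases(tl_params, config.tl_cases, rng, config.tl_shift_sd)
            flags = flag_below(ref, cases, threshold=config.tl_threshold)
            frac = sum(f for _, f in flags.values()) / len(flags)
            telomere_report = {
                "n_controls": ref.n_controls,
                "n_cases": len(flags),
                "fraction_below_threshold": frac,
                "mean_case_percentile": float(np.mean([p for p, _ in flags.values()])),
            }
            if out is not None:
                from .io import tl_records_to_df

                tl_records_to_df(controls).to_csv(out / "tl_controls.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        raise StageError(f"stage '{name}' failed: {exc}") from exc

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.canonical_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "thresholds": {
            "maf_threshold": config.maf_threshold,
            "tl_percentile_threshold": config.tl_threshold,
            "processivity_fit_window": "n >= 2",
            "tl_age_window_years": 5.0,
        },
    }
    bundle = ReportBundle(
        block=block_report,
        screen=screen_report,
        segregation=seg_reports,
        assay=assay_report,
        telomere=telomere_report,
        provenance=provenance,
    )
    if out is not None:
        (out / "report.json").write_text(bundle.to_json())
    return bundle


def _markers_from_truth(config: SimConfig, sites) -> MarkerSet:
    """MarkerSet for the planted markers on a freshly generated site list."""
    from .synthetic_data import _marker_site_indices, _site_positions

    idx = _marker_site_indices(config, _site_positions(config))
    markers = [sites[j] for j in idx]
    target = sites[config.target_index]
    left = [m for m in markers if m.pos < target.pos]
    right = [m for m in markers if m.pos > target.pos]
    return MarkerSet(
        markers=markers,
        marker_indices=idx,
        target=target,
        target_index=config.target_index,
        left_flank=left[-1] if left else None,
        right_flank=right[0] if right else None,
    )


def _cmp_dict(cmp) -> dict:
    return {
        "mean_percent_of_wt": cmp.mean_percent_of_wt,
        "sem_percent_of_wt": cmp.sem_percent_of_wt,
        "reduction_percent": cmp.reduction_percent,
        "p_value": cmp.p_value,
        "n_replicates": cmp.n_replicates,
    }
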