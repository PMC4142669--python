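"""End-to-end synthetic replication experiment.

``run_replicate`` generates a paired cohort (each animal contributing a
control and a regenerated nerve sharing an animal-level size effect), runs
both nerves through the light- and electron-microscopy pipelines
(detection filter -> systematic fields -> top-rule counts -> morphometry
-> density and total-number estimates), and performs the paired
comparisons: control vs crush for total fiber number and size parameters,
and LM vs EM total fiber number within each group.

All randomness descends from one master seed through stage-name-keyed
derivation, so a config reproduces its outputs exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import SectionCounts, count_section
from .detection import DetectionModel, apply_detection, em_detection, lm_detection
from .errors import ConfigError
from .estimation import StereologyEstimate, estimate
from .io import write_counts, write_estimates, write_frames, write_section
from .morphometry import measure_section_fibers
from .sampling import (
    SamplingDesign,
    attach_reference_areas,
    em_design,
    lm_design,
    make_frames,
    place_fields,
)
from .stats import PairedComparison, paired_t_test
from .synthetic import (
    DEFAULT_NERVE_RADIUS_UM,
    FiberPhenotypeParams,
    NerveSection,
    control_params,
    generate_section,
    regenerated_params,
)

__all__ = [
    "PipelineConfig",
    "ReplicateResult",
    "derive_seed",
    "run_section_estimate",
    "run_replicate",
]

TOP_CONVENTION = {"LM": "fiber", "EM": "axon"}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, keyed by stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one full replicate experiment."""

    n_animals: int = 5
    target_fiber_count: int = 1200
    nerve_radius_um: float = DEFAULT_NERVE_RADIUS_UM
    animal_effect_sigma: float = 0.05
    master_seed: int = 0
    lm: SamplingDesign = field(default_factory=lm_design)
    em: SamplingDesign = field(default_factory=em_design)
    lm_detection: DetectionModel = field(default_factory=lm_detection)
    em_detection: DetectionModel = field(default_factory=em_detection)
    area_noise_sigma: float = 0.0
    g_ratio_convention: str = "d_over_D"

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        if self.target_fiber_count < 1:
            raise ConfigError("target_fiber_count must be >= 1")
        if self.animal_effect_sigma < 0:
            raise ConfigError("animal_effect_sigma must be >= 0")

    def phenotype(self, group: str) -> FiberPhenotypeParams:
        if group == "control":
            return control_params(self.target_fiber_count)
        if group == "regenerated":
            return regenerated_params(self.target_fiber_count)
        raise ConfigError(f"unknown group {group!r}")


@dataclass
class ReplicateResult:
    """Everything one replicate run produced."""

    estimates: pd.DataFrame
    size_means: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict
    sections: dict = field(default_factory=dict)

    def comparison(self, name: str) -> pd.Series:
        rows = self.comparisons[self.comparisons["comparison"] == name]
        if len(rows) != 1:
            raise KeyError(name)
        return rows.iloc[0]


def run_section_estimate(
    section: NerveSection,
    design: SamplingDesign,
    detection: DetectionModel | None = None,
    placement_seed: int | None = None,
    detection_seed: int | None = None,
) -> tuple[StereologyEstimate, SectionCounts, list]:
    """Single-nerve pipeline: detect -> sample -> count -> estimate.

    The density denominator uses each frame's reference area (frame within
    the nerve); the total multiplies by the section's measured
    cross-sectional area, mirroring how the EM estimate reuses the
    LM-measured whole-nerve area.
    """
    visible = (
        section if detection is None else apply_detection(section, detection, detection_seed)
    )
    fields = place_fields(section, design, seed=placement_seed)
    frames = attach_reference_areas(make_frames(fields, design), section)
    counts = count_section(visible, frames, convention=TOP_CONVENTION[design.modality])
    est = estimate(
        counts,
        nerve_area_um2=section.cross_sectional_area,
        section_id=visible.section_id,
        modality=design.modality,
    )
    return est, counts, frames


def _comparison_row(c: PairedComparison, name: str) -> dict:
    return {
        "comparison": name,
        "n": c.n,
        "mean_a": c.mean_a,
        "sd_a": c.sd_a,
        "mean_b": c.mean_b,
        "sd_b": c.sd_b,
        "t": c.t_statistic,
        "df": c.degrees_of_freedom,
        "p": c.p_value,
        "tier": c.significance_tier,
    }


def run_replicate(
    config: PipelineConfig,
    out_dir: Path | str | None = None,
    *,
    keep_sections: bool = False,
) -> ReplicateResult:
    """Run the full synthetic experiment described by ``config``."""
    ms = config.master_seed
    animal_rng = np.random.default_rng(derive_seed(ms, "animal-effects"))
    multipliers = np.exp(
        animal_rng.normal(0.0, config.animal_effect_sigma, config.n_animals)
    )

    est_rows = []
    size_rows = []
    estimates: list[StereologyEstimate] = []
    sections: dict[tuple[int, str], NerveSection] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for i in range(config.n_animals):
        for group in ("control", "regenerated"):
            # the animal size effect scales the whole nerve: diameters and
            # nerve radius together, so the packing fraction stays constant
            params = config.phenotype(group).scaled(float(multipliers[i]))
            sec_seed = derive_seed(ms, f"section:{group}:{i}")
            section = generate_section(
                params,
                nerve_radius=config.nerve_radius_um * float(multipliers[i]),
                seed=sec_seed,
                section_id=f"animal{i}-{group}",
            )
            if keep_sections:
                sections[(i, group)] = section
            if out is not None:
                write_section(section, out / f"section_animal{i}_{group}.csv")

            for modality, design, det in (
                ("LM", config.lm, config.lm_detection),
                ("EM", config.em, config.em_detection),
            ):
                est, counts, frames = run_section_estimate(
                    section,
                    design,
                    detection=det,
                    placement_seed=derive_seed(ms, f"place:{modality}:{group}:{i}"),
                    detection_seed=derive_seed(ms, f"detect:{modality}:{group}:{i}"),
                )
                estimates.append(est)
                row = {
                    "animal": i,
                    "group": group,
                    "modality": modality,
                    "section_id": section.section_id,
                    "total_counted": est.total_counted,
                    "total_frame_area_um2": est.total_frame_area,
                    "density_per_mm2": est.density_per_mm2,
                    "nerve_area_um2": est.nerve_area_um2,
                    "total_fibers": est.total_fibers,
                    "true_fibers": section.n_fibers,
                }
                est_rows.append(row)
                if out is not None:
                    stem = f"animal{i}_{group}_{modality}"
                    write_frames(frames, out / f"frames_{stem}.csv")
                    write_counts(
                        counts,
                        out / f"counts_{stem}.csv",
                        out / f"counts_summary_{stem}.csv",
                    )
                if modality == "LM":
                    visible = apply_detection(section, det)
                    counted_ids = sorted(
                        {fid for r in counts.results for fid in r.counted_fiber_ids}
                    )
                    meas = measure_section_fibers(
                        visible,
                        counted_ids,
                        area_noise_sigma=config.area_noise_sigma,
                        rng=np.random.default_rng(
                            derive_seed(ms, f"measure:{group}:{i}")
                        ),
                        g_ratio_convention=config.g_ratio_convention,
                    )
                    if out is not None:
                        meas.to_csv(out / f"measurements_{stem}.csv", index=False)
                    size_rows.append(
                        {
                            "animal": i,
                            "group": group,
                            "n_measured": len(meas),
                            "d_um": meas["d_um"].mean(),
                            "D_um": meas["D_um"].mean(),
                            "myelin_um": meas["myelin_um"].mean(),
                            "g_ratio": meas["g_ratio"].mean(),
                        }
                    )

    est_df = pd.DataFrame(est_rows)
    size_df = pd.DataFrame(size_rows)

    def col(group, modality, column="total_fibers"):
        sel = est_df[(est_df["group"] == group) & (est_df["modality"] == modality)]
        return sel.sort_values("animal")[column].to_numpy()

    comp_rows = []
    comp_rows.append(
        _comparison_row(
            paired_t_test(
                col("control", "LM"), col("regenerated", "LM"), "control", "crush"
            ),
            "total_fibers:LM:control_vs_crush",
        )
    )
    comp_rows.append(
        _comparison_row(
            paired_t_test(
                col("control", "EM"), col("regenerated", "EM"), "control", "crush"
            ),
            "total_fibers:EM:control_vs_crush",
        )
    )
    for group in ("control", "regenerated"):
        comp_rows.append(
            _comparison_row(
                paired_t_test(col(group, "LM"), col(group, "EM"), "LM", "EM"),
                f"total_fibers:{group}:LM_vs_EM",
            )
        )
    for param in ("d_um", "D_um", "myelin_um", "g_ratio"):
        a = size_df[size_df["group"] == "control"].sort_values("animal")[param]
        b = size_df[size_df["group"] == "regenerated"].sort_values("animal")[param]
        comp_rows.append(
            _comparison_row(
                paired_t_test(a.to_numpy(), b.to_numpy(), "control", "crush"),
                f"{param}:LM:control_vs_crush",
            )
        )
    comp_df = pd.DataFrame(comp_rows)

    manifest = {
        "nervestereo_version": __version__,
        "master_seed": ms,
        "n_animals": config.n_animals,
        "groups": ["control", "regenerated"],
        "modalities": ["LM", "EM"],
        "n_estimates": len(estimates),
        "animal_size_multipliers": [float(m) for m in multipliers],
        "config": {
            "target_fiber_count": config.target_fiber_count,
            "nerve_radius_um": config.nerve_radius_um,
            "animal_effect_sigma": config.animal_effect_sigma,
            "area_noise_sigma": config.area_noise_sigma,
            "g_ratio_convention": config.g_ratio_convention,
            "lm_design": asdict(config.lm),
            "em_design": asdict(config.em),
            "lm_detection": asdict(config.lm_detection),
            "em_detection": asdict(config.em_detection),
        },
    }

    if out is not None:
        write_estimates(estimates, out / "estimates.csv")
        est_df.to_csv(out / "estimates_by_animal.csv", index=False)
        size_df.to_csv(out / "size_means_by_animal.csv", index=False)
        comp_df.to_csv(out / "comparisons.csv", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    return ReplicateResult(
        estimates=est_df,
        size_means=size_df,
        comparisons=comp_df,
        manifest=manifest,
        sections=sections,
    )
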