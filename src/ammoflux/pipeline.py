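"""End-to-end analysis pipeline over an observations table.

Stages: deconvolution + permeability estimation (diffusion strains),
equilibrium-ratio prediction with sensitivity bounds, and physiology
bookkeeping with consistency validation.  Each stage writes one tidy
CSV; a JSON manifest and a machine-parsable run log record versions,
seed and a configuration hash so reruns are auditable and hash-stable
(no timestamps enter any output).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compartments import (
    CellModel,
    MembraneEnergetics,
    SensitivityBox,
    ratio_bounds,
)
from .errors import AmmofluxError, UsageError
from .io import read_observations
from .physiology import (
    ATPStoichiometry,
    measured_ic_ec_ratio,
    physiology_summary,
    validate_observation,
)
from .transport import TransportParams, solve_steady_state

__all__ = ["RunConfig", "run_pipeline"]

_MECHANISMS = ("diffusion", "uniport")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    observations: Path
    output_dir: Path
    cell_model: CellModel = field(default_factory=CellModel.default)
    sensitivity_box: SensitivityBox = field(default_factory=SensitivityBox)
    energetics: MembraneEnergetics = field(default_factory=MembraneEnergetics)
    transport: TransportParams = field(default_factory=TransportParams)
    stoichiometry: ATPStoichiometry = field(default_factory=ATPStoichiometry)
    strain_mechanisms: tuple[tuple[str, str], ...] = (
        ("IMZ351", "diffusion"),
        ("IME169", "uniport"),
    )
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for strain, mechanism in self.strain_mechanisms:
            if mechanism not in _MECHANISMS:
                raise UsageError(
                    f"unknown mechanism {mechanism!r} for strain {strain!r}"
                )

    def mechanism_of(self, strain: str) -> str | None:
        for name, mechanism in self.strain_mechanisms:
            if name == strain:
                return mechanism
        return None

    def config_hash(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages and write one CSV per stage plus a manifest.

    Any stage failure aborts with a stage-tagged diagnostic after
    flushing partial outputs next to a ``FAILED`` marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"version={__version__}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]
    results: dict[str, pd.DataFrame] = {}
    stage = "load"
    try:
        observations = read_observations(config.observations)
        log_lines.append(f"stage=load n_observations={len(observations)}")

        stage = "deconvolve"
        rows = []
        for obs in observations:
            if config.mechanism_of(obs.strain) != "diffusion":
                continue
            sol = solve_steady_state(
                obs, config.cell_model, config.transport, config.sensitivity_box
            )
            rows.append(
                {
                    "strain": sol.strain,
                    "pH_EC": sol.ph_ec,
                    "nh3_cyt_umolL": sol.nh3_cyt_umol,
                    "nh3_ec_umolL": sol.nh3_ec_umol,
                    "permeability_m_per_h": sol.permeability,
                    "adjusted": sol.adjusted or "",
                    "feasible": sol.feasible,
                }
            )
            log_lines.append(
                f"stage=deconvolve strain={sol.strain} pH={sol.ph_ec:g} "
                f"feasible={sol.feasible} adjusted={sol.adjusted or 'none'}"
            )
        results["steady_state"] = pd.DataFrame(rows)

        stage = "predict-ratios"
        rows = []
        ph_values = sorted({obs.ph_ec for obs in observations})
        for mechanism in _MECHANISMS:
            for ph in ph_values:
                bounds = ratio_bounds(
                    mechanism, ph, config.sensitivity_box, config.cell_model,
                    config.energetics,
                )
                rows.append(
                    {
                        "mechanism": mechanism,
                        "pH_EC": ph,
                        "ratio_min": bounds.minimum,
                        "ratio_max": bounds.maximum,
                    }
                )
        results["predicted_ratios"] = pd.DataFrame(rows)

        stage = "physiology"
        rows = []
        for obs in observations:
            summary = physiology_summary(obs, config.stoichiometry)
            report = validate_observation(obs, stoich=config.stoichiometry)
            rows.append(
                {
                    "strain": obs.strain,
                    "pH_EC": obs.ph_ec,
                    "Y_XS_gGlc": summary.y_xs,
                    "CN_CmolNmol": summary.cn_ratio,
                    "qATP_mmolgh": summary.q_atp,
                    "qATPperN_molmol": summary.qatp_per_qn,
                    "measured_IC_EC_ratio": measured_ic_ec_ratio(
                        obs.nhx_ic, obs.nhx_ec
                    ),
                    "validation_flags": "; ".join(report.flags),
                }
            )
            if report.flags:
                log_lines.append(
                    f"stage=physiology strain={obs.strain} pH={obs.ph_ec:g} "
                    f"flags={len(report.flags)}"
                )
        results["physiology"] = pd.DataFrame(rows)
    except AmmofluxError as exc:
        for name, frame in results.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n", encoding="utf-8")
        raise AmmofluxError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for name, frame in results.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(results),
        "outputs": [f"{name}.csv" for name in results],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return results
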