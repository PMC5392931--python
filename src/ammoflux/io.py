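"""Table readers/writers and configuration loading.

The observations CSV schema is fixed, with units embedded in the column
names to prevent silent unit drift::

    strain,pH_EC,mu_1ph,qS_mmolgh,qO2_mmolgh,qCO2_mmolgh,qEtOH_mmolgh,
    qN_mmolgh,Ncontent_mmolg,biomass_gL,cellvol_mLg,NHX_IC_mM,NHX_EC_mM

Four optional columns carry tabulated derived physiology for
cross-checks: ``YXS_gGlc,CN_CmolNmol,qATP_mmolgh,qATPperN_molmol``.
Dialect: comma separated, dot decimal, UTF-8, header required.

The package ships the reference dataset (six strain x pH steady states
of two S. cerevisiae strains - IME169 with ammonium permeases, IMZ351
with all three Mep permeases deleted - from nitrogen-limited aerobic
chemostats at dilution rate 0.05 1/h) as a fixture; see
:func:`load_reference_observations`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .compartments import CellModel, Compartment, MembraneEnergetics, SensitivityBox
from .errors import DomainError, ParseError
from .physiology import ChemostatObservation, PhysiologySummary
from .speciation import AcidBaseParams
from .transport import TransportParams

__all__ = [
    "OBSERVATION_COLUMNS",
    "read_observations",
    "write_observations",
    "load_reference_observations",
    "load_model_config",
    "default_model_config",
]

OBSERVATION_COLUMNS: dict[str, str] = {
    "strain": "strain",
    "pH_EC": "ph_ec",
    "mu_1ph": "mu",
    "qS_mmolgh": "q_s",
    "qO2_mmolgh": "q_o2",
    "qCO2_mmolgh": "q_co2",
    "qEtOH_mmolgh": "q_etoh",
    "qN_mmolgh": "q_n",
    "Ncontent_mmolg": "n_content",
    "biomass_gL": "biomass_conc",
    "cellvol_mLg": "cell_volume",
    "NHX_IC_mM": "nhx_ic",
    "NHX_EC_mM": "nhx_ec",
}

_REPORTED_COLUMNS: dict[str, str] = {
    "YXS_gGlc": "y_xs",
    "CN_CmolNmol": "cn_ratio",
    "qATP_mmolgh": "q_atp",
    "qATPperN_molmol": "qatp_per_qn",
}


def read_observations(path: str | Path) -> list[ChemostatObservation]:
    """Read and validate a chemostat observations CSV.

    Every offending cell (missing column, non-numeric value, violated
    invariant) is collected and reported with its line number in a
    single :class:`~ammoflux.errors.ParseError`.  An empty file with
    only the header yields an empty list.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # header missing / unreadable
        raise ParseError(f"could not read {path}: {exc}") from exc
    problems: list[str] = []
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns", [", ".join(missing)])
    has_reported = all(c in frame.columns for c in _REPORTED_COLUMNS)
    observations: list[ChemostatObservation] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        kwargs: dict = {}
        row_ok = True
        for column, attr in OBSERVATION_COLUMNS.items():
            value = row[column]
            if attr == "strain":
                kwargs[attr] = str(value)
                continue
            try:
                kwargs[attr] = float(value)
            except (TypeError, ValueError):
                problems.append(f"line {line}, column {column}: non-numeric {value!r}")
                row_ok = False
        if not row_ok:
            continue
        reported = None
        if has_reported:
            try:
                reported = PhysiologySummary(
                    **{attr: float(row[col]) for col, attr in _REPORTED_COLUMNS.items()}
                )
            except (TypeError, ValueError, DomainError) as exc:
                problems.append(f"line {line}: bad reported columns: {exc}")
                continue
        try:
            observations.append(ChemostatObservation(reported=reported, **kwargs))
        except DomainError as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ParseError(f"{path}: invalid observation table", problems)
    return observations


def write_observations(
    observations: Iterable[ChemostatObservation], path: str | Path
) -> None:
    """Write observations in the fixed CSV schema (round-trips with
    :func:`read_observations`)."""
    rows = []
    observations = list(observations)
    include_reported = all(o.reported is not None for o in observations)
    for o in observations:
        row = {col: getattr(o, attr) for col, attr in OBSERVATION_COLUMNS.items()}
        if include_reported:
            row.update(
                {col: getattr(o.reported, attr) for col, attr in _REPORTED_COLUMNS.items()}
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _data_path(name: str):
    return importlib.resources.files("ammoflux") / "data" / name


def load_reference_observations() -> list[ChemostatObservation]:
    """The packaged reference dataset: six strain x pH chemostat steady
    states with tabulated derived physiology attached."""
    with importlib.resources.as_file(_data_path("chemostat_reference.csv")) as p:
        return read_observations(p)


def _pair(value, label: str) -> tuple[float, float]:
    lo, hi = value
    return float(lo), float(hi)


def load_model_config(path: str | Path) -> dict:
    """Load a cell model, sensitivity box, energetics and transport
    parameters from a YAML config.

    Returns a dict with keys ``cell_model``, ``sensitivity_box``,
    ``energetics`` and ``transport`` (missing sections fall back to
    package defaults).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    acid_base = AcidBaseParams(
        pka=float(raw.get("acid_base", {}).get("pka", AcidBaseParams().pka)),
        temperature_K=float(
            raw.get("acid_base", {}).get("temperature_K", AcidBaseParams().temperature_K)
        ),
    )
    if "compartments" in raw:
        compartments = tuple(
            Compartment(
                name=str(c["name"]),
                volume_fraction=float(c["volume_fraction"]),
                ph=float(c["ph"]),
            )
            for c in raw["compartments"]
        )
        cell_model = CellModel(compartments=compartments, acid_base=acid_base)
    else:
        cell_model = CellModel.default(acid_base)
    box_raw = raw.get("sensitivity_box", {})
    box = SensitivityBox(
        vacuole_fraction=_pair(
            box_raw.get("vacuole_fraction", SensitivityBox().vacuole_fraction),
            "vacuole_fraction",
        ),
        cytosol_ph=_pair(box_raw.get("cytosol_ph", SensitivityBox().cytosol_ph), "cytosol_ph"),
        vacuole_ph=_pair(box_raw.get("vacuole_ph", SensitivityBox().vacuole_ph), "vacuole_ph"),
    )
    energetics_raw = raw.get("energetics", {})
    energetics = MembraneEnergetics(
        pmf_mV=float(energetics_raw.get("pmf_mV", MembraneEnergetics().pmf_mV))
    )
    transport_raw = raw.get("transport", {})
    transport = TransportParams(
        a_m=float(transport_raw.get("a_m_m2_per_g", TransportParams().a_m)),
        chi_n=float(transport_raw.get("chi_n_mol_per_g", TransportParams().chi_n)),
        mu_max=(
            float(transport_raw["mu_max_1ph"]) if "mu_max_1ph" in transport_raw else None
        ),
    )
    return {
        "cell_model": cell_model,
        "sensitivity_box": box,
        "energetics": energetics,
        "transport": transport,
    }


def default_model_config() -> dict:
    """The packaged default model configuration."""
    with importlib.resources.as_file(_data_path("default_model.yaml")) as p:
        return load_model_config(p)
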