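"""File formats: curve CSV, model/protocol/electrode/spec JSON.

Curves are CSV with columns ``volume_mL, emf_mV[, pH]``; ``#``-prefixed
header lines carry ``key: value`` metadata (seed, noise levels, V0).
Models are JSON with keys ``species`` (list of {m, h, l, log_beta,
label}), ``pKw``, ``medium``, ``temperature_C``, ``ionic_strength_M``.
Volumes are mL, concentrations mol/L, EMF mV throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import CurveParseError, InvalidModelError
from .model import EquilibriumModel, SpeciesDef
from .refine import RefinementSpec
from .titration import Electrode, TitrationCurve, TitrationProtocol

__all__ = [
    "read_curve", "write_curve",
    "read_model", "write_model",
    "read_protocol", "write_protocol",
    "read_electrode", "write_electrode",
    "read_refinement_spec",
]


def write_curve(curve: TitrationCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in sorted(curve.meta.items())]
    cols = "volume_mL,emf_mV" + (",pH" if curve.pH is not None else "")
    lines.append(cols)
    for i in range(len(curve)):
        row = f"{curve.v[i]!r},{curve.E[i]!r}"
        if curve.pH is not None:
            row += f",{curve.pH[i]!r}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path, electrode: Electrode | None = None) -> TitrationCurve:
    """Read a curve CSV.

    A file carrying only a pH column (no EMF) is accepted when an
    ``electrode`` is supplied to synthesize EMF via the Nernst response.
    """
    path = Path(path)
    meta: dict = {}
    header = None
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                try:
                    meta[k.strip()] = json.loads(v.strip())
                except json.JSONDecodeError:
                    meta[k.strip()] = v.strip()
            continue
        if header is None:
            header = [h.strip() for h in line.split(",")]
            if "volume_mL" not in header:
                raise CurveParseError("missing column volume_mL", line=lineno)
            if "emf_mV" not in header and "pH" not in header:
                raise CurveParseError("need emf_mV or pH column", line=lineno)
            continue
        vals = line.split(",")
        if len(vals) != len(header):
            raise CurveParseError(
                f"expected {len(header)} fields, got {len(vals)}", line=lineno)
        try:
            rows.append({h: float(x) for h, x in zip(header, vals)})
        except ValueError as exc:
            raise CurveParseError(str(exc), line=lineno) from None
    if header is None or not rows:
        raise CurveParseError("no data rows found")
    df = pd.DataFrame(rows)
    v = df["volume_mL"].to_numpy()
    if (v[1:] <= v[:-1]).any():
        bad = int((v[1:] <= v[:-1]).argmax()) + 2
        raise CurveParseError("volumes not strictly increasing", line=bad)
    if "emf_mV" in df:
        E = df["emf_mV"].to_numpy()
        ph = df["pH"].to_numpy() if "pH" in df else None
    else:
        if electrode is None:
            raise CurveParseError(
                "file has only a pH column; an electrode is required to "
                "synthesize EMF")
        ph = df["pH"].to_numpy()
        E = electrode.emf(ph)
    return TitrationCurve(v=tuple(v), E=tuple(E),
                          pH=tuple(ph) if ph is not None else None, meta=meta)


def write_model(model: EquilibriumModel, path: str | Path) -> None:
    doc = {
        "species": [
            {"m": sp.m, "h": sp.h, "l": sp.l,
             "log_beta": sp.log_beta, "label": sp.label}
            for sp in model.species
        ],
        "pKw": model.pKw,
        "medium": model.medium,
        "temperature_C": model.temperature_C,
        "ionic_strength_M": model.ionic_strength_M,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_model(path: str | Path) -> EquilibriumModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InvalidModelError(f"invalid JSON in {path}: {exc}") from None
    if "pKw" not in doc:
        raise InvalidModelError(f"{path}: missing required key 'pKw'")
    if "species" not in doc or not isinstance(doc["species"], list):
        raise InvalidModelError(f"{path}: missing species list")
    species = []
    for i, s in enumerate(doc["species"]):
        try:
            species.append(SpeciesDef(
                m=int(s["m"]), h=int(s["h"]), l=int(s["l"]),
                log_beta=float(s["log_beta"]), label=str(s.get("label", "")),
            ))
        except KeyError as exc:
            raise InvalidModelError(
                f"{path}: species[{i}] missing key {exc}") from None
    return EquilibriumModel(
        species=tuple(species),
        pKw=float(doc["pKw"]),
        medium=str(doc.get("medium", "")),
        temperature_C=float(doc.get("temperature_C", 25.0)),
        ionic_strength_M=float(doc.get("ionic_strength_M", 0.1)),
    )


def write_protocol(protocol: TitrationProtocol, path: str | Path) -> None:
    doc = {
        "V0": protocol.V0, "C_L0": protocol.C_L0, "C_M0": protocol.C_M0,
        "C_acid0": protocol.C_acid0, "C_titrant": protocol.C_titrant,
        "ligand_protons": protocol.ligand_protons,
        "volumes": list(protocol.volumes),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_protocol(path: str | Path) -> TitrationProtocol:
    doc = json.loads(Path(path).read_text())
    return TitrationProtocol(
        V0=float(doc.get("V0", 20.0)),
        C_L0=float(doc.get("C_L0", 0.0)),
        C_M0=float(doc.get("C_M0", 0.0)),
        C_acid0=float(doc.get("C_acid0", 2e-3)),
        C_titrant=float(doc.get("C_titrant", 0.1)),
        ligand_protons=int(doc.get("ligand_protons", 3)),
        volumes=tuple(float(x) for x in doc.get("volumes", ())),
    )


def write_electrode(electrode: Electrode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"E0": electrode.E0, "slope": electrode.slope}, indent=2) + "\n")


def read_electrode(path: str | Path) -> Electrode:
    doc = json.loads(Path(path).read_text())
    return Electrode(E0=float(doc["E0"]), slope=float(doc["slope"]))


def read_refinement_spec(path: str | Path) -> RefinementSpec:
    doc = json.loads(Path(path).read_text())
    kwargs = dict(
        free_params=tuple(doc["free_params"]),
        initial_guesses={k: float(v)
                         for k, v in doc.get("initial_guesses", {}).items()},
        sigma_E=float(doc.get("sigma_E", 0.1)),
        sigma_v=float(doc.get("sigma_v", 0.002)),
        convergence_tol=float(doc.get("convergence_tol", 1e-8)),
        max_iter=int(doc.get("max_iter", 100)),
        residual=str(doc.get("residual", "emf")),
    )
    if doc.get("max_pH") is not None:
        kwargs["max_pH"] = float(doc["max_pH"])
    return RefinementSpec(**kwargs)
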