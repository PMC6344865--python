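"""Plain-text file formats: binned traces, burst tables, scheme configs, reports.

Traces are tab-separated ``time_s  donor  acceptor  acceptor_direct`` with
``# key=value`` header lines carrying bin width, gamma and condition metadata.
Burst tables are ``burst_id  n_donor  n_acceptor  n_acceptor_direct``.  Kinetic
and thermodynamic ground-truth schemes live in a small versioned YAML schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .bursts import BinnedDualTrace, Burst
from .errors import DataError
from .scheme import KineticScheme, StateSpec, ThermoGroundTruth
from .simulate import BurstSet

SCHEME_VERSION = 1

_META_CASTS = {
    "bin_width_s": float,
    "gamma": float,
    "pressure_bar": float,
    "temperature_K": float,
}


def write_trace(trace: BinnedDualTrace, path: str | Path) -> None:
    path = Path(path)
    meta = {"bin_width_s": trace.bin_width, **trace.metadata}
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
    with path.open("w") as fh:
        fh.write(header + "\n")
        fh.write("# time_s\tdonor\tacceptor\tacceptor_direct\n")
        for t, d, a, ad in zip(
            trace.times, trace.donor, trace.acceptor, trace.acceptor_direct
        ):
            fh.write(f"{t:.6f}\t{d}\t{a}\t{ad}\n")


def read_trace(path: str | Path) -> BinnedDualTrace:
    path = Path(path)
    meta: dict = {}
    donor, acceptor, direct = [], [], []
    bin_width = None
    prev_t = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" not in token:
                        continue
                    key, val = token.split("=", 1)
                    meta[key] = _META_CASTS.get(key, str)(val)
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                t = float(fields[0])
                counts = [int(f) for f in fields[1:]]
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise DataError(f"{path}:{lineno}: negative photon count")
            if prev_t is not None:
                dt = t - prev_t
                if bin_width is None:
                    bin_width = dt
                elif abs(dt - bin_width) > 1e-9:
                    raise DataError(
                        f"{path}:{lineno}: inconsistent bin width "
                        f"({dt:.6g} vs {bin_width:.6g})"
                    )
            prev_t = t
            donor.append(counts[0])
            acceptor.append(counts[1])
            direct.append(counts[2])
    if not donor:
        raise DataError(f"{path}: no data rows")
    bw = meta.pop("bin_width_s", bin_width if bin_width else 1e-3)
    return BinnedDualTrace(
        bin_width=bw,
        donor=np.array(donor),
        acceptor=np.array(acceptor),
        acceptor_direct=np.array(direct),
        metadata=meta,
    )


def write_bursts(bursts, path: str | Path) -> None:
    path = Path(path)
    if isinstance(bursts, BurstSet):
        rows = zip(bursts.n_d, bursts.n_a, bursts.n_a_direct)
    else:
        rows = ((b.n_d, b.n_a, b.n_a_direct) for b in bursts)
    with path.open("w") as fh:
        fh.write("# burst_id\tn_donor\tn_acceptor\tn_acceptor_direct\n")
        for i, (d, a, ad) in enumerate(rows):
            fh.write(f"{i}\t{d}\t{a}\t{ad}\n")


def read_bursts(path: str | Path) -> list[Burst]:
    path = Path(path)
    bursts = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                _bid, d, a, ad = (int(f) for f in fields)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            if min(d, a, ad) < 0:
                raise DataError(f"{path}:{lineno}: negative photon count")
            bursts.append(Burst(n_d=d, n_a=a, n_a_direct=ad, span=(lineno, lineno)))
    if not bursts:
        raise DataError(f"{path}: no data rows")
    return bursts


def write_scheme(
    scheme: KineticScheme,
    path: str | Path,
    thermo: ThermoGroundTruth | None = None,
) -> None:
    doc: dict = {
        "version": SCHEME_VERSION,
        "states": [
            {"label": s.label, "e_mean": float(s.e_mean), "e_sd": float(s.e_sd)}
            for s in scheme.states
        ],
        "rates": [float(r) for r in scheme.rates.ravel()],  # row-major
    }
    if thermo is not None:
        doc["thermo"] = {
            "delta_v_cm3_mol": thermo.delta_v,
            "keq_ref": thermo.keq_ref,
            "p_ref_bar": thermo.p_ref,
            "temperature_K": thermo.temperature,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scheme(
    path: str | Path,
) -> tuple[KineticScheme, ThermoGroundTruth | None]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "states" not in doc:
        raise DataError(f"{path}: not a scheme file")
    if doc.get("version", 1) != SCHEME_VERSION:
        raise DataError(f"{path}: unsupported scheme version {doc.get('version')}")
    states = tuple(
        StateSpec(s["label"], float(s["e_mean"]), float(s["e_sd"]))
        for s in doc["states"]
    )
    n = len(states)
    rates = np.asarray(doc["rates"], dtype=float).reshape(n, n)
    scheme = KineticScheme(states=states, rates=rates)
    thermo = None
    if "thermo" in doc:
        t = doc["thermo"]
        thermo = ThermoGroundTruth(
            delta_v=float(t["delta_v_cm3_mol"]),
            keq_ref=float(t["keq_ref"]),
            p_ref=float(t.get("p_ref_bar", 1.0)),
            temperature=float(t.get("temperature_K", 298.15)),
        )
    return scheme, thermo


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
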