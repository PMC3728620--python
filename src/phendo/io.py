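"""Trace and config I/O, run manifests, and deterministic test fixtures.

Traces are stored as diff-able TSV: comment lines carry the protocol
(JSON), seed and metadata; the body has ``time_s`` and ``dF`` columns.
Floats are written with ``repr`` precision so a write/read round trip is
exact.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import yaml

from .protocols import Burst, StimulusProtocol
from .simulate import FluorescenceTrace, TraceMeta


class TraceFormatError(ValueError):
    pass


def _protocol_to_json(p: StimulusProtocol) -> str:
    d = {
        "bursts": [[b.n_ap, b.freq, b.onset] for b in p.bursts],
        "temperature": p.temperature,
        "ca_mM": p.ca_mM,
        "condition": p.condition,
        "trace_duration": p.trace_duration,
        "sample_interval": p.sample_interval,
        "post_window": p.post_window,
    }
    return json.dumps(d, separators=(",", ":"))


def _protocol_from_json(s: str) -> StimulusProtocol:
    d = json.loads(s)
    return StimulusProtocol(
        bursts=tuple(Burst(int(n), float(f), float(o)) for n, f, o in d["bursts"]),
        temperature=d["temperature"],
        ca_mM=float(d["ca_mM"]),
        condition=d["condition"],
        trace_duration=float(d["trace_duration"]),
        sample_interval=float(d["sample_interval"]),
        post_window=float(d.get("post_window", 30.0)),
    )


def write_trace(trace: FluorescenceTrace, path) -> None:
    path = pathlib.Path(path)
    lines = [
        f"# protocol={_protocol_to_json(trace.protocol)}",
        f"# seed={trace.meta.rng_seed}",
        f"# cell_id={trace.meta.cell_id}",
        f"# genotype={trace.meta.genotype}",
        "time_s\tdF",
    ]
    for t, y in zip(trace.t, trace.dF):
        lines.append(f"{float(t)!r}\t{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> FluorescenceTrace:
    path = pathlib.Path(path)
    text = path.read_text()
    if not text.strip():
        raise TraceFormatError(f"{path}: empty trace file")
    header: dict[str, str] = {}
    t_vals: list[float] = []
    f_vals: list[float] = []
    saw_columns = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                header[key.strip()] = val.strip()
            continue
        if not saw_columns:
            cols = line.split("\t")
            if cols[:2] != ["time_s", "dF"]:
                raise TraceFormatError(f"{path}:{lineno}: expected header 'time_s\\tdF'")
            saw_columns = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TraceFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            t_vals.append(float(parts[0]))
            f_vals.append(float(parts[1]))
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric value") from exc
    if "protocol" not in header:
        raise TraceFormatError(f"{path}: missing '# protocol=' comment line")
    if not t_vals:
        raise TraceFormatError(f"{path}: no data rows")
    t = np.asarray(t_vals)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise TraceFormatError(f"{path}: time column must be strictly increasing")
    seed = header.get("seed")
    meta = TraceMeta(
        cell_id=header.get("cell_id", "cell0"),
        genotype=header.get("genotype", "control"),
        rng_seed=int(seed) if seed not in (None, "None") else None,
    )
    return FluorescenceTrace(
        t=t, dF=np.asarray(f_vals), protocol=_protocol_from_json(header["protocol"]), meta=meta
    )


def read_traces(path) -> list[FluorescenceTrace]:
    """Read all ``*.tsv`` traces from a directory, or a single file."""
    path = pathlib.Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tsv"))
        if not files:
            raise TraceFormatError(f"{path}: no .tsv trace files found")
        return [read_trace(f) for f in files]
    return [read_trace(path)]


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_default_config(name: str = "37C") -> dict:
    """Shipped default parameter set: ``"37C"``, ``"30C"`` or ``"37C_mouse"``."""
    fname = f"defaults_{name}.yaml"
    ref = resources.files("phendo").joinpath("defaults", fname)
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record for a batch of outputs: config hash, seeds, files."""

    config_hash: str
    seed: int
    package_version: str = ""
    entries: list[dict] = field(default_factory=list)

    def add(self, command: str, output: str, **extra) -> None:
        self.entries.append({"command": command, "output": output, **extra})

    def write(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int, out_dir=None):
    """Canonical small synthetic dataset used by the test suite.

    Three cells probed at 5, 25 and 100 AP (10 Hz), each as a noiseless
    trace (the deterministic ensemble-mean trace, so the recorded
    ground-truth kinetics are exactly recoverable) and a stochastic
    noisy trace, plus one bafilomycin trace; ground-truth kinetics are
    recorded in a JSON sidecar.  Byte-identical for a fixed seed.
    Returns (traces, params) and also writes TSV files if ``out_dir``
    is given.
    """
    from .calibrate import calibrate_defaults, cell_from_config
    from .protocols import single_burst
    from .simulate import expected_trace, simulate_trace

    cfg = calibrate_defaults()["37C"]
    base = cell_from_config(cfg)
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3 * 3 + 1)
    tau1s = [base.tau1 * f for f in (0.8, 1.0, 1.25)]
    traces: dict[str, FluorescenceTrace] = {}
    params: dict[str, dict] = {}
    k = 0
    for ci, tau1 in enumerate(tau1s):
        cell = base.replace(tau1=tau1)
        params[f"cell{ci}"] = {"tau1": cell.tau1, "slope_m": cell.slope_m,
                               "alpha_max": cell.alpha_max, "delta_a": cell.delta_a}
        for n_ap in (5, 25, 100):
            prot = single_burst(n_ap, 10.0)
            clean = expected_trace(cell.replace(noise_sd=0.0), prot)
            clean.meta = TraceMeta(cell_id=f"cell{ci}", rng_seed=None)
            traces[f"cell{ci}_{n_ap}ap_clean"] = clean
            noisy = simulate_trace(cell, prot, seeds[k])
            noisy.meta = TraceMeta(cell_id=f"cell{ci}", rng_seed=seed)
            traces[f"cell{ci}_{n_ap}ap_noisy"] = noisy
            k += 1
    baf_prot = single_burst(1000, 10.0, condition="bafilomycin", post_window=30.0)
    # pool exhaustion is the point of the saturating pool-size assay
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        baf = simulate_trace(base.replace(noise_sd=0.0), baf_prot, seeds[k])
    traces["cell0_baf_1000ap"] = baf

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tr in traces.items():
            write_trace(tr, out / f"{name}.tsv")
        (out / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
    return traces, params


def fixtures_checksum(seed: int) -> str:
    """Digest of the full fixture set (regeneration determinism check)."""
    traces, params = make_fixtures(seed)
    h = hashlib.sha256()
    for name in sorted(traces):
        tr = traces[name]
        h.update(name.encode())
        h.update(tr.t.tobytes())
        h.update(tr.dF.tobytes())
    h.update(json.dumps(params, sort_keys=True).encode())
    return h.hexdigest()
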