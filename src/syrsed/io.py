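"""Tabular text output with provenance headers.

Every file carries the package version, the configuration hash and
the RNG seed (when one applies) as commented header lines, so a run
can be reproduced bit-for-bit from its outputs.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version

import numpy as np

from .sim import SimResult
from .specs import ConcentrationCurve

__all__ = ["package_version", "write_curve", "read_curve", "write_sim_result"]


def package_version() -> str:
    try:
        return version("syrsed")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def _header(kind: str, provenance: dict = None) -> str:
    lines = [f"syrsed {kind}", f"version: {package_version()}"]
    for k, v in (provenance or {}).items():
        lines.append(f"{k}: {v}")
    return "\n".join(lines)


def write_curve(path, curve: ConcentrationCurve, provenance: dict = None) -> None:
    """Write a concentration curve as two-column text (time_s, ratio)."""
    prov = {"source": curve.source}
    for k, v in curve.meta.items():
        if isinstance(v, (int, float, str, bool)):
            prov[k] = v
    prov.update(provenance or {})
    np.savetxt(
        path,
        np.column_stack([curve.times, curve.ratio]),
        header=_header("concentration curve", prov) + "\ntime_s ratio",
    )


def read_curve(path, source: str = "measured") -> ConcentrationCurve:
    data = np.loadtxt(path)
    return ConcentrationCurve(times=data[:, 0], ratio=data[:, 1], source=source)


def write_sim_result(path, r: SimResult, provenance: dict = None) -> None:
    """Write per-particle fates as text: event kind (1=captured,
    2=exited) and event time, one row per finished particle."""
    prov = {
        "n_initial": r.n_initial,
        "n_exited": len(r.exit_times),
        "n_captured": len(r.capture_times),
        "n_suspended": r.n_suspended,
        "seed": r.config.seed,
        "dt_s": r.config.dt,
        "max_time_s": r.config.max_time,
        "integrator": r.config.integrator,
    }
    prov.update(provenance or {})
    kinds = np.concatenate(
        [np.full(len(r.capture_times), 1), np.full(len(r.exit_times), 2)]
    )
    times = np.concatenate([r.capture_times, r.exit_times])
    order = np.argsort(times, kind="stable")
    np.savetxt(
        path,
        np.column_stack([kinds[order], times[order]]),
        fmt=["%d", "%.6f"],
        header=_header("particle fates", prov) + "\nkind time_s",
    )
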