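"""Mixing reports: JSON-canonical result containers with CSV mirrors.

A report bundles every metric computed for one ROI/sample together with
provenance (input hash, configuration, seed, package version, timestamp) so
that any number in it can be traced back to one operation on one input.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

from .concentration import IntensityStats, LengthScale, VariogramResult
from .particles import MpResult, SegregationSummary

SCHEMA_VERSION = 1

__all__ = ["MixingReport", "SCHEMA_VERSION", "file_sha256"]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _variogram_block(v: VariogramResult, ls: LengthScale | None) -> dict[str, Any]:
    block: dict[str, Any] = {
        "axis": v.axis,
        "lags": [int(h) for h in v.lags],
        "gamma": [float(g) for g in v.gamma],
        "pair_counts": [int(c) for c in v.pair_counts],
    }
    if ls is not None:
        block["length_scale"] = float(ls.value)
        block["length_scale_attained"] = bool(ls.attained)
    return block


@dataclass
class MixingReport:
    """All metrics for one ROI/sample, exportable to JSON and CSV."""

    mode: str
    provenance: dict[str, Any] = field(default_factory=dict)
    concentration: dict[str, Any] = field(default_factory=dict)
    particles: dict[str, Any] = field(default_factory=dict)
    error: str | None = None
    schema_version: int = SCHEMA_VERSION

    # ---- builders -------------------------------------------------------

    @staticmethod
    def provenance_block(
        inputs: dict[str, str] | None = None,
        config: dict[str, Any] | None = None,
        seed: int | None = None,
    ) -> dict[str, Any]:
        from . import __version__

        prov: dict[str, Any] = {
            "package": "micromix",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        if inputs:
            prov["inputs"] = {
                name: {"path": str(p), "sha256": file_sha256(p)}
                for name, p in inputs.items()
                if Path(p).exists()
            }
        if config is not None:
            prov["config"] = config
        if seed is not None:
            prov["seed"] = seed
        return prov

    def add_intensity(self, stats: IntensityStats) -> None:
        block = {"Cm": stats.cm, "sigma": stats.sigma}
        try:
            block["CoV"] = stats.cov
            block["M"] = stats.mixing_index
        except ValueError:
            block["CoV"] = block["M"] = None
        try:
            block["I"] = stats.intensity
        except ValueError:
            block["I"] = None
        self.concentration.update(block)

    def add_exposure(self, e: float) -> None:
        self.concentration["E"] = e

    def add_variogram(
        self, v: VariogramResult, ls: LengthScale | None = None
    ) -> None:
        key = "LH" if v.axis == "horizontal" else "LV"
        self.concentration.setdefault("variograms", {})[v.axis] = _variogram_block(v, ls)
        if ls is not None:
            self.concentration[key] = float(ls.value)

    def add_summary(self, s: SegregationSummary) -> None:
        self.particles.update(
            {
                "P": s.count,
                "CoV": s.cov,
                "MST": s.mst,
                "sigma_fpp": s.sigma_fpp,
                "Idisp": s.idisp,
                "SR": s.sr,
            }
        )

    def add_mp(self, r: MpResult) -> None:
        self.particles["mp"] = r.mp
        self.particles["ratios"] = {
            "Idisp": r.idisp_ratio,
            "SR": r.sr_ratio,
            "sigma_fpp": r.sigma_fpp_ratio,
        }

    # ---- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MixingReport":
        data = json.loads(Path(path).read_text())
        return cls(
            mode=data.get("mode", "unknown"),
            provenance=data.get("provenance", {}),
            concentration=data.get("concentration", {}),
            particles=data.get("particles", {}),
            error=data.get("error"),
            schema_version=data.get("schema_version", SCHEMA_VERSION),
        )

    def write_csv(self, path: str | Path) -> None:
        """Flat scalar metrics as a two-column CSV; variogram tables go to
        sibling files ``<stem>_variogram_<axis>.csv``."""
        path = Path(path)
        rows: list[tuple[str, Any]] = []
        for section in ("concentration", "particles"):
            block = getattr(self, section)
            for key, value in block.items():
                if isinstance(value, (int, float)) or value is None:
                    rows.append((f"{section}.{key}", value))
                elif key == "ratios":
                    rows.extend(
                        (f"{section}.ratio.{k}", v) for k, v in value.items()
                    )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            writer.writerows(rows)
        for axis, table in self.concentration.get("variograms", {}).items():
            vpath = path.with_name(f"{path.stem}_variogram_{axis}.csv")
            with open(vpath, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["lag", "gamma", "pair_count"])
                writer.writerows(
                    zip(table["lags"], table["gamma"], table["pair_counts"])
                )
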