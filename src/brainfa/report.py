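"""Human-readable summaries and run manifests for the analysis pipeline."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

__all__ = ["RunManifest", "render_report"]


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance sidecar: identical inputs reproduce identical outputs."""

    command: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    row_counts: dict = field(default_factory=dict)
    seed: int | None = None

    def add_input(self, path: str) -> None:
        self.inputs[str(path)] = _digest(path)

    def write(self, path: str) -> None:
        from . import __version__

        payload = {
            "tool": "brainfa",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "python": platform.python_version(),
            "command": self.command,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest(),
            "seed": self.seed,
            "inputs": self.inputs,
            "row_counts": self.row_counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fmt_pct(x: float) -> str:
    if pd.isna(x):
        return "n/a"
    mag = abs(round(x))
    word = "increase" if x > 0 else ("decrease" if x < 0 else "no change")
    return f"{mag:.0f}% {word}"


def render_report(comparison: pd.DataFrame | None,
                  correlation: pd.DataFrame | None = None) -> str:
    """Markdown summary: per-region pre-FDR hits and post-FDR survivors.

    Mirrors the convention of reporting star-coded raw significance
    separately from discoveries that survive BH adjustment. Deterministic
    for identical inputs.
    """
    lines = ["# Regional fatty-acid aging summary", ""]
    if comparison is None or comparison.empty:
        lines += ["No comparison results.", ""]
    else:
        lines += ["## Middle-aged vs elderly comparison", ""]
        for region, grp in comparison.groupby("region", sort=False):
            lines.append(f"### {region}")
            hits = grp[grp["sig_flags"] != ""]
            if hits.empty:
                lines.append("- no variables significant before FDR")
            else:
                for _, row in hits.iterrows():
                    lines.append(
                        f"- {row['variable']}: {_fmt_pct(row['pct_change'])} "
                        f"(p = {row['p_raw']:.3g} {row['sig_flags']}, "
                        f"q = {row['q_adj']:.3g})")
            surv = grp[grp["discovery"]]
            names = ", ".join(surv["variable"]) if not surv.empty else "none"
            lines.append(f"- FDR survivors: {names}")
            lines.append("")
    if correlation is not None and not correlation.empty:
        lines += ["## Age-continuum correlations", ""]
        for region, grp in correlation.groupby("region", sort=False):
            lines.append(f"### {region}")
            hits = grp[grp["p_raw"] < 0.05]
            if hits.empty:
                lines.append("- no significant correlations with age")
            else:
                for _, row in hits.iterrows():
                    lines.append(
                        f"- {row['variable']}: rho = {row['rho']:+.2f} "
                        f"(p = {row['p_raw']:.3g}, q = {row['q_adj']:.3g})")
            surv = grp[grp["discovery"]]
            names = ", ".join(surv["variable"]) if not surv.empty else "none"
            lines.append(f"- FDR survivors: {names}")
            lines.append("")
    return "\n".join(lines).rstrip() + "\n"
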