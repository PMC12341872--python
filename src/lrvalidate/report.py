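"""Validation reports: human-readable table and machine-readable JSON.

The machine-readable form has a fixed key order and repr-exact floats, so
identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .ci import IntervalResult

__all__ = ["ValidationReport", "STATISTIC_ORDER"]

STATISTIC_ORDER = (
    "bias",
    "dispersion",
    "ratio_of_accuracies",
    "reliability",
    "predictivity",
)


@dataclass
class ValidationReport:
    """Per-trait statistic -> interval (or bare estimate) plus run metadata."""

    traits: dict[int, dict[str, IntervalResult]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, trait: int, statistic: str, result: IntervalResult) -> None:
        if statistic not in STATISTIC_ORDER:
            raise ValueError(f"unknown statistic {statistic!r}")
        self.traits.setdefault(trait, {})[statistic] = result

    def to_dict(self) -> dict:
        out = {"metadata": dict(sorted(self.metadata.items())), "traits": {}}
        for trait in sorted(self.traits):
            block = {}
            for name in STATISTIC_ORDER:
                if name not in self.traits[trait]:
                    continue
                r = self.traits[trait][name]
                entry = {"estimate": r.estimate}
                if r.se is not None:
                    entry["se"] = r.se
                if r.mode != "none":
                    entry["lower"] = r.lower
                    entry["upper"] = r.upper
                    entry["mode"] = r.mode
                block[name] = entry
            out["traits"][str(trait)] = block
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = []
        meta = self.metadata
        lines.append("LR-method validation report")
        if meta:
            bits = [f"{k}={v}" for k, v in sorted(meta.items())]
            lines.append("  " + "  ".join(bits))
        has_ci = any(
            r.mode != "none"
            for block in self.traits.values()
            for r in block.values()
        )
        for trait in sorted(self.traits):
            lines.append(f"trait {trait}")
            if has_ci:
                lines.append(
                    f"  {'statistic':<22}{'estimate':>14}{'SE':>14}"
                    f"{'lower95':>14}{'upper95':>14}"
                )
            else:
                lines.append(f"  {'statistic':<22}{'estimate':>14}")
            for name in STATISTIC_ORDER:
                if name not in self.traits[trait]:
                    continue
                r = self.traits[trait][name]
                if has_ci:
                    se = f"{r.se:14.6g}" if r.se is not None else " " * 13 + "-"
                    lines.append(
                        f"  {name:<22}{r.estimate:14.6g}{se}"
                        f"{r.lower:14.6g}{r.upper:14.6g}"
                    )
                else:
                    lines.append(f"  {name:<22}{r.estimate:14.6g}")
        return "\n".join(lines) + "\n"
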