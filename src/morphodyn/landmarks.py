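"""Landmark configurations, sliding-semilandmark specifications, and TPS I/O.

TPS is the plain-text interchange format produced by the tpsDig family of
digitising tools: blocks of ``LM=k`` followed by k whitespace-separated
``x y`` lines and trailing key=value lines (``ID=``, ``IMAGE=``, ``SCALE=``).
Only 2D configurations are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class LandmarkConfiguration:
    """One taxon's ordered 2D landmark coordinates."""

    taxon: str
    coords: np.ndarray  # (k, 2)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"{self.taxon}: coords must be (k, 2)")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def centroid_size(self) -> float:
        centered = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((centered ** 2).sum()))


@dataclass
class SlidingSpec:
    """Curves of landmark indices; interior indices are semilandmarks.

    Endpoints of each curve are fixed anatomical landmarks; the interior
    points are allowed to slide along the curve during superimposition.
    """

    curves: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        seen: set[int] = set()
        for curve in self.curves:
            if len(curve) < 3:
                raise ValueError("a sliding curve needs >= 3 points")
            if len(set(curve)) != len(curve):
                raise ValueError(f"repeated index within curve {curve}")
            interior = curve[1:-1]
            if seen & set(interior):
                raise ValueError("a semilandmark may belong to only one curve")
            seen.update(interior)

    @property
    def semilandmarks(self) -> list[int]:
        out: list[int] = []
        for curve in self.curves:
            out.extend(curve[1:-1])
        return out

    def validate_for(self, k: int) -> None:
        for curve in self.curves:
            if any(i < 0 or i >= k for i in curve):
                raise ValueError(f"curve index out of range for k={k}: {curve}")

    def flanks(self) -> dict[int, tuple[int, int]]:
        """Map each semilandmark index to its flanking point indices."""
        out: dict[int, tuple[int, int]] = {}
        for curve in self.curves:
            for pos in range(1, len(curve) - 1):
                out[curve[pos]] = (curve[pos - 1], curve[pos + 1])
        return out


# ----------------------------------------------------------------------
# TPS I/O
# ----------------------------------------------------------------------
def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS file into a list of landmark configurations.

    The taxon name is taken from the ``ID=`` line, falling back to ``IMAGE=``
    and finally to the block's ordinal position.  All blocks must share the
    same landmark count.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    block_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"{path}: expected LM= at line {i + 1}, got {line!r}")
        block_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed LM= line {i + 1}: {line!r}") from exc
        i += 1
        coords = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise ValueError(f"{path}: block {block_no} truncated")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: malformed coordinate line {i + 1}: {lines[i]!r}")
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed coordinate line {i + 1}: {lines[i]!r}"
                ) from exc
            i += 1
        taxon = None
        image = None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            upper = stripped.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("ID="):
                taxon = stripped.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                image = stripped.split("=", 1)[1].strip()
            elif "=" not in stripped:
                raise ValueError(f"{path}: malformed line {i + 1}: {stripped!r}")
            i += 1
        name = taxon or image or f"specimen_{block_no}"
        configs.append(LandmarkConfiguration(taxon=name, coords=coords))

    if not configs:
        raise ValueError(f"{path}: no landmark blocks found")
    k0 = configs[0].k
    for b, cfg in enumerate(configs, start=1):
        if cfg.k != k0:
            raise ValueError(
                f"{path}: block {b} has {cfg.k} landmarks, expected {k0}")
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.k}\n")
            for x, y in cfg.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={cfg.taxon}\n")
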