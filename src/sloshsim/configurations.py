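"""The 57-configuration study suite: baseline, isolated and expanding syringes.

The 285 mm syrinx region is segmented into 28 axial segments (twenty-seven
10 mm segments and one 15 mm segment at the caudal end).  Each segment is
either fluid (part of a syrinx) or intact cord tissue:

* ``baseline`` — no fluid segments;
* ``S<i>`` — exactly segment ``i`` fluid, syrinx radius a fixed fraction
  (default 0.70) of the local cord radius;
* ``S1-<j>`` — segments ``1..j`` fluid, radii following the smooth
  MRI-like envelope of the anatomy profile.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import DEFAULT_SEGMENT_LENGTHS, AnatomyProfile
from .errors import ValidationError

N_SEGMENTS = 28

FIXED_RATIO = "fixed_ratio"
MRI_LIKE = "mri_like"
NO_SYRINX = "none"

_NAME_RE_SINGLE = re.compile(r"^S_?(\d+)$")
_NAME_RE_EXPAND = re.compile(r"^S_?1[-–](\d+)$")


def segment_extent(
    i: int, segment_lengths_mm: tuple[float, ...] = DEFAULT_SEGMENT_LENGTHS
) -> tuple[float, float]:
    """Axial extent [mm] of segment ``i`` (1-based).

    At the default segmentation: ``[(i-1)*10, i*10]`` for ``i <= 27`` and
    ``[270, 285]`` for the caudal 15 mm segment ``i = 28``.
    """
    n = len(segment_lengths_mm)
    if not (isinstance(i, (int, np.integer)) and 1 <= i <= n):
        raise ValidationError(f"segment index {i} out of range 1..{n}")
    starts = np.concatenate([[0.0], np.cumsum(segment_lengths_mm)])
    return float(starts[i - 1]), float(starts[i])


@dataclass(frozen=True)
class SyrinxPattern:
    """Which of the 28 segments hold fluid, and the radius rule applied there."""

    occupancy: tuple[bool, ...]
    radius_rule: str
    ratio: float = 0.70
    name: str = ""

    def validate(self) -> None:
        if len(self.occupancy) != N_SEGMENTS:
            raise ValidationError(f"occupancy must have {N_SEGMENTS} entries")
        if self.radius_rule not in (FIXED_RATIO, MRI_LIKE, NO_SYRINX):
            raise ValidationError(f"unknown radius rule {self.radius_rule!r}")
        if not 0.0 < self.ratio < 1.0:
            raise ValidationError(f"ratio {self.ratio} must lie in (0, 1)")
        if self.radius_rule == NO_SYRINX and any(self.occupancy):
            raise ValidationError("baseline pattern cannot occupy segments")

    @property
    def n_fluid(self) -> int:
        return sum(self.occupancy)

    def fluid_length_mm(
        self, segment_lengths_mm: tuple[float, ...] = DEFAULT_SEGMENT_LENGTHS
    ) -> float:
        return float(
            sum(s for s, occ in zip(segment_lengths_mm, self.occupancy) if occ)
        )

    def extent_mm(
        self, segment_lengths_mm: tuple[float, ...] = DEFAULT_SEGMENT_LENGTHS
    ) -> tuple[float, float] | None:
        """Union extent (x_start, x_end) of occupied segments, or None."""
        idx = [i + 1 for i, occ in enumerate(self.occupancy) if occ]
        if not idx:
            return None
        return (
            segment_extent(idx[0], segment_lengths_mm)[0],
            segment_extent(idx[-1], segment_lengths_mm)[1],
        )

    @classmethod
    def baseline(cls) -> "SyrinxPattern":
        return cls((False,) * N_SEGMENTS, NO_SYRINX, name="baseline")

    @classmethod
    def single(cls, i: int, ratio: float = 0.70) -> "SyrinxPattern":
        if not 1 <= i <= N_SEGMENTS:
            raise ValidationError(f"segment index {i} out of range 1..{N_SEGMENTS}")
        occ = tuple(k == i - 1 for k in range(N_SEGMENTS))
        return cls(occ, FIXED_RATIO, ratio=ratio, name=f"S{i}")

    @classmethod
    def expanding(cls, j: int) -> "SyrinxPattern":
        if not 1 <= j <= N_SEGMENTS:
            raise ValidationError(f"segment index {j} out of range 1..{N_SEGMENTS}")
        occ = tuple(k < j for k in range(N_SEGMENTS))
        return cls(occ, MRI_LIKE, name=f"S1-{j}")

    @classmethod
    def from_name(cls, name: str) -> "SyrinxPattern":
        name = name.strip()
        if name.lower() == "baseline":
            return cls.baseline()
        m = _NAME_RE_EXPAND.match(name)
        if m:
            return cls.expanding(int(m.group(1)))
        m = _NAME_RE_SINGLE.match(name)
        if m:
            return cls.single(int(m.group(1)))
        raise ValidationError(
            f"unrecognized configuration name {name!r}; expected 'baseline', "
            "'S<i>' or 'S1-<j>'"
        )


@dataclass
class ModelConfig:
    """An anatomy profile with a syrinx pattern applied.

    ``r_syrinx_effective_mm`` is positive exactly on the stations covered by
    occupied segments (closed extents; adjacent segments share their common
    boundary station).
    """

    anatomy: AnatomyProfile
    pattern: SyrinxPattern
    r_syrinx_effective_mm: np.ndarray

    @property
    def name(self) -> str:
        return self.pattern.name

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.r_syrinx_effective_mm > 0

    @property
    def area_syrinx_mm2(self) -> np.ndarray:
        return np.pi * self.r_syrinx_effective_mm**2

    @property
    def area_cord_annulus_mm2(self) -> np.ndarray:
        return np.pi * (self.anatomy.r_cord_mm**2 - self.r_syrinx_effective_mm**2)


def apply_pattern(
    anatomy: AnatomyProfile,
    pattern: SyrinxPattern,
    segment_lengths_mm: tuple[float, ...] = DEFAULT_SEGMENT_LENGTHS,
    taper_cells: int = 1,
) -> ModelConfig:
    """Build a ModelConfig by assigning fluid radii on occupied stations.

    With ``taper_cells > 1`` the radius is additionally ramped down over that
    many stations at each fluid/tissue interface; the default single-cell
    taper is supplied implicitly by the staggered-grid area averaging in the
    solver, which closes the cavity over one grid cell.
    """
    pattern.validate()
    x = anatomy.x_mm
    mask = np.zeros_like(x, dtype=bool)
    for i, occ in enumerate(pattern.occupancy, start=1):
        if occ:
            lo, hi = segment_extent(i, segment_lengths_mm)
            mask |= (x >= lo - 1e-9) & (x <= hi + 1e-9)

    if pattern.radius_rule == FIXED_RATIO:
        r_eff = np.where(mask, pattern.ratio * anatomy.r_cord_mm, 0.0)
    elif pattern.radius_rule == MRI_LIKE:
        r_eff = np.where(mask, anatomy.r_syrinx_max_mm, 0.0)
    else:
        r_eff = np.zeros_like(x)

    if np.any(mask & (r_eff <= 0)):
        k = int(np.argmax(mask & (r_eff <= 0)))
        raise ValidationError(
            f"radius rule yields non-positive syrinx radius at x = {x[k]} mm"
        )
    if taper_cells > 1 and mask.any():
        ramp = np.ones_like(r_eff)
        idx = np.where(mask)[0]
        # contiguous fluid blocks
        breaks = np.where(np.diff(idx) > 1)[0]
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        for s, e in zip(starts, ends):
            n = min(taper_cells, (e - s + 1) // 2)
            for k in range(n):
                f = (k + 1) / (n + 1)
                ramp[s + k] = min(ramp[s + k], f)
                ramp[e - k] = min(ramp[e - k], f)
        r_eff = r_eff * ramp
    return ModelConfig(anatomy=anatomy, pattern=pattern, r_syrinx_effective_mm=r_eff)


def make_baseline(anatomy: AnatomyProfile, **kw) -> ModelConfig:
    return apply_pattern(anatomy, SyrinxPattern.baseline(), **kw)


def make_single_syrinx(i: int, anatomy: AnatomyProfile, ratio: float = 0.70, **kw) -> ModelConfig:
    """Isolated small syrinx occupying segment ``i`` at the fixed radius ratio."""
    return apply_pattern(anatomy, SyrinxPattern.single(i, ratio=ratio), **kw)


def make_expanding_syrinx(j: int, anatomy: AnatomyProfile, **kw) -> ModelConfig:
    """Cranially seeded syrinx grown caudally through segment ``j`` (MRI-like radii)."""
    return apply_pattern(anatomy, SyrinxPattern.expanding(j), **kw)


def enumerate_suite(anatomy: AnatomyProfile, **kw) -> list[ModelConfig]:
    """The full ordered study suite: baseline, S1..S28, S1-1..S1-28 (57 runs)."""
    configs = [make_baseline(anatomy, **kw)]
    configs += [make_single_syrinx(i, anatomy, **kw) for i in range(1, N_SEGMENTS + 1)]
    configs += [make_expanding_syrinx(j, anatomy, **kw) for j in range(1, N_SEGMENTS + 1)]
    return configs


def config_kind(pattern: SyrinxPattern) -> str:
    if pattern.radius_rule == NO_SYRINX:
        return "baseline"
    if pattern.radius_rule == FIXED_RATIO:
        return "single"
    return "expanding"


def suite_manifest_table(configs: list[ModelConfig]) -> pd.DataFrame:
    """Suite manifest: ``name, kind, x_start_mm, x_end_mm, length_mm``."""
    rows = []
    for cfg in configs:
        ext = cfg.pattern.extent_mm()
        rows.append(
            {
                "name": cfg.name,
                "kind": config_kind(cfg.pattern),
                "x_start_mm": ext[0] if ext else np.nan,
                "x_end_mm": ext[1] if ext else np.nan,
                "length_mm": cfg.pattern.fluid_length_mm(),
            }
        )
    return pd.DataFrame(rows)
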