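"""Study orchestration: parameter files, calibration, the 57-run suite, reports.

``run_suite`` executes the baseline first (its profile is the shaded
reference in every figure), then the 28 isolated-syrinx configurations
S1..S28 and the 28 expansion stages S1-1..S1-28, writing per-run field
containers (HDF5), per-run profiles and the summary tables.  Everything is
randomness-free and resumable: completed runs are identified by a parameter
digest and skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import AnatomyParams, AnatomyProfile, synthesize_anatomy
from .configurations import (
    ModelConfig,
    SyrinxPattern,
    apply_pattern,
    config_kind,
    enumerate_suite,
    suite_manifest_table,
)
from .errors import ValidationError
from .materials import (
    ExcitationSpec,
    MaterialSet,
    NumericsOptions,
    derive_coefficients,
)
from .solver import SimulationResult, assemble, peak_stress, run
from .stress import (
    StressProfile,
    StressSummary,
    peak_stress_map,
    regional_table,
    slice_medians,
    summarize,
)

log = logging.getLogger("sloshsim")

SCHEMA_VERSION = 1
CALIBRATION_BAND_PA = (180.0, 360.0)


@dataclass(frozen=True)
class StudyParams:
    """Complete, serializable parameter set for a study."""

    anatomy: AnatomyParams = AnatomyParams()
    materials: MaterialSet = MaterialSet()
    excitation: ExcitationSpec = ExcitationSpec()
    numerics: NumericsOptions = NumericsOptions()

    def to_dict(self) -> dict:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        return {
            "schema_version": SCHEMA_VERSION,
            "anatomy": enc(self.anatomy),
            "materials": enc(self.materials),
            "excitation": enc(self.excitation),
            "numerics": enc(self.numerics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyParams":
        if d.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported parameter schema version {d.get('schema_version')}"
            )

        def dec(klass, sub):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name in sub:
                    v = sub[f.name]
                    if isinstance(v, list):
                        v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                    kwargs[f.name] = v
            return klass(**kwargs)

        return cls(
            anatomy=dec(AnatomyParams, d.get("anatomy", {})),
            materials=dec(MaterialSet, d.get("materials", {})),
            excitation=dec(ExcitationSpec, d.get("excitation", {})),
            numerics=dec(NumericsOptions, d.get("numerics", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "StudyParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        self.anatomy.validate()
        self.materials.validate()
        self.excitation.validate()
        self.numerics.validate()


def default_params() -> StudyParams:
    return StudyParams()


def smoke_params() -> StudyParams:
    """Reduced-resolution preset (2 mm grid, 0.25 s) for quick passes.

    The caudal terminus moves to 341 mm so the 2 mm grid divides the span.
    """
    p = StudyParams()
    anatomy = dataclasses.replace(
        p.anatomy.with_grid_spacing(2.0), total_length_mm=341.0
    )
    return dataclasses.replace(
        p,
        anatomy=anatomy,
        numerics=dataclasses.replace(p.numerics, dx_mm=2.0, duration_s=0.25),
    )


@dataclass
class CalibrationRecord:
    gamma: float
    achieved_pa: float
    band_pa: tuple[float, float]
    params_digest: str


@dataclass
class SuiteManifest:
    names: list[str]
    paths: dict[str, str]
    params_digest: str
    version: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "result_path": [self.paths[n] for n in self.names],
                "params_digest": self.params_digest,
                "version": self.version,
            }
        )


def _resolved_anatomy(params: StudyParams) -> AnatomyProfile:
    anat_params = params.anatomy
    if abs(anat_params.grid_spacing_mm - params.numerics.dx_mm) > 1e-12:
        anat_params = anat_params.with_grid_spacing(params.numerics.dx_mm)
    return synthesize_anatomy(anat_params)


def run_config(
    config: ModelConfig | str,
    params: StudyParams | None = None,
    anatomy: AnatomyProfile | None = None,
    store_fields: bool = True,
) -> SimulationResult:
    """Simulate one configuration (by object or by name) at the given params."""
    params = params or default_params()
    params.validate()
    if isinstance(config, str):
        anatomy = anatomy if anatomy is not None else _resolved_anatomy(params)
        config = apply_pattern(
            anatomy,
            SyrinxPattern.from_name(config),
            params.anatomy.segment_lengths_mm,
            taper_cells=params.numerics.taper_cells,
        )
    coeffs = derive_coefficients(params.materials, config, params.numerics)
    system = assemble(config, coeffs, params.materials, params.numerics)
    log.info("running %s (dt = %.3g s, %d stations)", config.name, system.dt, len(system.x))
    return run(system, params.excitation, store_fields=store_fields)


def profile_from_result(
    result: SimulationResult, config: ModelConfig, params: StudyParams
) -> StressProfile:
    coeffs = derive_coefficients(params.materials, config, params.numerics)
    pmap = peak_stress_map(peak_stress(result, coeffs), result.x_mm)
    # 1 mm slices at the default grid; coarser presets widen the slices to
    # the grid pitch so every slice holds at least one element
    width = max(1.0, params.numerics.dx_mm)
    return slice_medians(
        pmap, width_mm=width, region_bounds_mm=config.anatomy.region_bounds_mm
    )


def calibrate(
    band_pa: tuple[float, float] = CALIBRATION_BAND_PA,
    params: StudyParams | None = None,
    write_path: str | Path | None = None,
) -> CalibrationRecord:
    """Fix the stress-scale gamma from a baseline run.

    Runs the syrinx-free configuration with gamma = 1, measures the maximum
    slice-median raw stress, and scales gamma so the calibrated value sits at
    the band midpoint.  Pure rescaling, hence idempotent: recalibrating with
    the resulting gamma returns the same gamma.
    """
    if not (0 < band_pa[0] <= band_pa[1]):
        raise ValidationError("calibration band must be positive and ordered")
    params = params or default_params()
    raw_params = dataclasses.replace(
        params, numerics=dataclasses.replace(params.numerics, gamma=1.0)
    )
    anatomy = _resolved_anatomy(raw_params)
    config = apply_pattern(anatomy, SyrinxPattern.baseline())
    result = run_config(config, raw_params, anatomy, store_fields=False)
    profile = profile_from_result(result, config, raw_params)
    raw_max = float(np.max(profile.value_pa))
    if raw_max <= 0:
        raise ValidationError("baseline run produced zero stress; cannot calibrate")
    target = 0.5 * (band_pa[0] + band_pa[1])
    gamma = target / raw_max
    record = CalibrationRecord(
        gamma=gamma,
        achieved_pa=gamma * raw_max,
        band_pa=band_pa,
        params_digest=params.digest(),
    )
    if write_path is not None:
        calibrated = dataclasses.replace(
            params, numerics=dataclasses.replace(params.numerics, gamma=gamma)
        )
        calibrated.save(write_path)
    return record


def run_suite(
    out_dir: str | Path,
    params: StudyParams | None = None,
    smoke: bool = False,
    resume: bool = True,
    configs: list[str] | None = None,
    store_fields: bool = True,
) -> SuiteManifest:
    """Execute the full study suite and write all summary tables.

    Outputs under ``out_dir``: per-run ``<name>.h5`` field containers and
    ``<name>_profile.csv`` slice profiles, ``suite_manifest.csv``,
    ``singles_table.csv`` (sigma_max/delta_sigma per isolated syrinx),
    ``expansion_table.csv`` (peak location vs caudal end per expansion stage)
    and ``percent_increase_stats.json``.
    """
    params = params or (smoke_params() if smoke else default_params())
    params.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = params.digest()
    anatomy = _resolved_anatomy(params)
    suite = enumerate_suite(
        anatomy,
        segment_lengths_mm=params.anatomy.segment_lengths_mm,
        taper_cells=params.numerics.taper_cells,
    )
    if configs is not None:
        wanted = set(configs)
        suite = [c for c in suite if c.name in wanted]
        missing = wanted - {c.name for c in suite}
        if missing:
            raise ValidationError(f"unknown configuration names: {sorted(missing)}")

    names: list[str] = []
    paths: dict[str, str] = {}
    profiles: dict[str, StressProfile] = {}
    for config in suite:
        h5_path = out / f"{config.name}.h5"
        if resume and h5_path.exists():
            try:
                cached = SimulationResult.load(str(h5_path))
                if cached.meta.get("params_digest") == digest:
                    log.info("skipping completed run %s", config.name)
                    result = cached
                else:
                    result = None
            except OSError:
                result = None
        else:
            result = None
        if result is None:
            result = run_config(config, params, anatomy, store_fields=store_fields)
            result.meta["params_digest"] = digest
            result.save(str(h5_path))
        profile = profile_from_result(result, config, params)
        profile.to_frame().to_csv(out / f"{config.name}_profile.csv", index=False)
        names.append(config.name)
        paths[config.name] = str(h5_path)
        profiles[config.name] = profile

    manifest = SuiteManifest(names=names, paths=paths, params_digest=digest, version=__version__)
    mf = manifest.to_frame().merge(
        suite_manifest_table(suite), on="name", how="left"
    )
    mf.to_csv(out / "suite_manifest.csv", index=False)

    if "baseline" in profiles:
        _write_tables(out, params, suite, profiles)
    return manifest


def _write_tables(out: Path, params: StudyParams, suite, profiles) -> None:
    baseline = profiles["baseline"]
    singles: dict[str, StressSummary] = {}
    expansion_rows = []
    for config in suite:
        if config.name == "baseline" or config.name not in profiles:
            continue
        extent = config.pattern.extent_mm(params.anatomy.segment_lengths_mm)
        s = summarize(config.name, profiles[config.name], baseline, extent)
        if config_kind(config.pattern) == "single":
            singles[config.name] = s
        else:
            expansion_rows.append(
                {
                    "name": s.name,
                    "sigma_max_pa": s.sigma_max_pa,
                    "x_at_max_mm": s.x_at_max_mm,
                    "caudal_end_mm": extent[1],
                    "distance_to_caudal_end_mm": abs(s.x_at_max_mm - extent[1]),
                    "delta_sigma_pa": s.delta_sigma_pa,
                }
            )
    if singles:
        regional_table(singles, list(singles)).to_csv(
            out / "singles_table.csv", index=False
        )
        pct = np.asarray([s.percent_increase for s in singles.values()])
        stats = {
            "n": int(len(pct)),
            "min_percent": float(np.min(pct)),
            "max_percent": float(np.max(pct)),
            "median_percent": float(np.median(pct)),
        }
        (out / "percent_increase_stats.json").write_text(json.dumps(stats, indent=2))
    if expansion_rows:
        pd.DataFrame(expansion_rows).to_csv(out / "expansion_table.csv", index=False)


def load_profiles(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = Path(out_dir)
    profiles = {}
    for p in sorted(out.glob("*_profile.csv")):
        profiles[p.name[: -len("_profile.csv")]] = pd.read_csv(p)
    return profiles


def report(out_dir: str | Path, fig_dir: str | Path | None = None) -> list[Path]:
    """Render the suite figures: shaded-baseline profile panels for the
    isolated and expanding syringes, sigma_max / delta_sigma bars by position
    with C/T/L dividers, and the caudal-peak trajectory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_dir = Path(fig_dir) if fig_dir else out / "figures"
    manifest_path = out / "suite_manifest.csv"
    if not manifest_path.exists():
        raise ValidationError(f"no suite manifest in {out}; run the suite first")
    profiles = load_profiles(out)
    if "baseline" not in profiles:
        raise ValidationError("baseline profile missing; cannot render reports")
    fig_dir.mkdir(parents=True, exist_ok=True)
    base = profiles["baseline"]
    written: list[Path] = []

    panel_groups = {
        "singles_profiles.png": [["S1"], ["S8"], ["S15"], ["S25"]],
        "expansion_profiles.png": [
            [f"S1-{j}" for j in range(1, 5)],
            [f"S1-{j}" for j in range(5, 11)],
            [f"S1-{j}" for j in range(11, 19)],
            [f"S1-{j}" for j in range(19, 29)],
        ],
    }
    for fname, groups in panel_groups.items():
        present = [[n for n in g if n in profiles] for g in groups]
        if not any(present):
            continue
        fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True, sharey=True)
        for ax, group in zip(axes.ravel(), present):
            ax.fill_between(base["x_mm"], 0, base["median_peak_stress_pa"], alpha=0.3)
            for i, n in enumerate(group):
                lw = 2.0 if i == len(group) - 1 else 0.8
                ax.plot(
                    profiles[n]["x_mm"],
                    profiles[n]["median_peak_stress_pa"],
                    "k-",
                    lw=lw,
                )
            ax.set_title(", ".join(group) if group else "(missing)")
            ax.set_xlabel("x [mm]")
            ax.set_ylabel("median peak stress [Pa]")
        fig.tight_layout()
        path = fig_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    singles_path = out / "singles_table.csv"
    if singles_path.exists():
        tab = pd.read_csv(singles_path)
        pos = [10 * int(n[1:]) - 5 for n in tab["name"]]
        fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
        axes[0].bar(pos, tab["sigma_max_pa"], width=8)
        axes[0].set_ylabel("sigma_max [Pa]")
        axes[1].bar(pos, tab["delta_sigma_pa"], width=8)
        axes[1].set_ylabel("delta_sigma [Pa]")
        axes[1].set_xlabel("syrinx position [mm]")
        for ax in axes:
            for b in (85.0, 230.0):
                ax.axvline(b, ls="--", c="gray")
        fig.tight_layout()
        path = fig_dir / "singles_bars.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    expansion_path = out / "expansion_table.csv"
    if expansion_path.exists():
        tab = pd.read_csv(expansion_path)
        fig, ax = plt.subplots(figsize=(8, 5))
        ax.plot(tab["caudal_end_mm"], tab["x_at_max_mm"], "o-")
        ax.plot([0, 285], [0, 285], "--", c="gray", label="peak at caudal end")
        ax.set_xlabel("syrinx caudal end [mm]")
        ax.set_ylabel("location of peak stress [mm]")
        ax.legend()
        fig.tight_layout()
        path = fig_dir / "expansion_peak_trajectory.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
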