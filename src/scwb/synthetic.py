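"""Ground-truthed synthetic single-cell western blot (scWB) data.

A scWB lane is a 1-mm polyacrylamide separation axis along which each
protein species in a single-cell lysate migrates a distance set by its
molecular mass (log-linearly, at fixed gel density) and is detected as a
roughly Gaussian fluorescence band.  This module simulates per-lane
intensity profiles with known truth (per-cell loads, band centers and
widths, planted subpopulations, planted marker-space cluster structure)
so that every downstream stage of the pipeline can be tested without the
original slide scans.

Positions are micrometres from the microwell edge; intensities are
arbitrary fluorescence units (AFU); per-cell protein abundance ("load")
is the analytic area of the band in AFU*um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MigrationModel",
    "ProteinSpecies",
    "Subpopulation",
    "ClusterComponent",
    "SimulationConfig",
    "migration_distance",
    "simulate_profile",
    "generate_cohort",
    "render_slide_image",
    "make_layout",
    "bt474_migration_model",
    "bt474_preset",
    "tumor_preset",
    "simulate_marker_mixture",
    "config_from_file",
    "BT474_PEAK_STATS",
    "lognormal_params",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)

#: Printed BT474 peak statistics (mean, SD) used by the separation-resolution
#: study: electromigration distance L and FWHM, in um, for the full-length
#: p185HER2 band and the truncated t-erbB2 band.
BT474_PEAK_STATS = {
    "p185": {"center": (99.3, 15.7), "fwhm": (93.7, 22.0)},
    "terbb2": {"center": (188.2, 18.1), "fwhm": (120.7, 30.0)},
}


@dataclass(frozen=True)
class MigrationModel:
    """Log-linear mass-to-migration map for a fixed gel density.

    distance(M) = intercept_a - slope_b * log10(M), distances in um,
    masses in kDa.  slope_b > 0, so heavier species migrate less far.
    """

    intercept_a: float
    slope_b: float
    axis_length: float = 1000.0

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive")
        if self.axis_length <= 0:
            raise ValueError("axis_length must be positive")

    def distance(self, mass_kda: float) -> float:
        if mass_kda <= 0:
            raise ValueError(f"mass must be positive, got {mass_kda}")
        return self.intercept_a - self.slope_b * math.log10(mass_kda)

    def mass_at(self, distance_um: float) -> float:
        return 10.0 ** ((self.intercept_a - distance_um) / self.slope_b)

    def in_range(self, distance_um: float) -> bool:
        return 0.0 < distance_um < self.axis_length


def migration_distance(mass_kda: float, model: MigrationModel) -> float:
    """Predicted electromigration distance (um) of a species of given mass."""
    return model.distance(mass_kda)


def bt474_migration_model(axis_length: float = 1000.0) -> MigrationModel:
    """Migration model solved from the observed BT474 band centers.

    Anchored on the two measured bands: full-length p185HER2
    (185 kDa at 99.3 um) and the ~128.7 kDa truncated form at 188.2 um.
    """
    m1, d1 = 185.0, 99.3
    m2, d2 = 128.7, 188.2
    b = (d2 - d1) / (math.log10(m1) - math.log10(m2))
    a = d1 + b * math.log10(m1)
    return MigrationModel(intercept_a=a, slope_b=b, axis_length=axis_length)


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the natural-log normal with the given mean and CV."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


@dataclass(frozen=True)
class ProteinSpecies:
    """One simulated protein target in a lane.

    mean_load is the expected band area (AFU*um); per-cell loads are
    lognormal with coefficient of variation load_cv.  center_sd_um adds
    per-cell migration jitter (clipped at 2 SD so planted bands stay
    inside their detection windows); min_snr, if set, floors the drawn
    load so the band amplitude is at least min_snr times the configured
    noise SD.
    """

    name: str
    mass_kda: float
    mean_load: float
    load_cv: float = 0.3
    sigma_um: float = 20.0
    channel: str = "ch1"
    probe_round: int = 1
    center_sd_um: float = 0.0
    min_snr: float | None = None
    center_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError("mass_kda must be positive")
        if self.mean_load < 0 or self.load_cv < 0 or self.sigma_um <= 0:
            raise ValueError("invalid species parameters")


@dataclass(frozen=True)
class Subpopulation:
    """A planted cell subpopulation carrying extra species (e.g. t-erbB2)."""

    label: str
    fraction: float
    extra_species: tuple[ProteinSpecies, ...] = ()


@dataclass(frozen=True)
class ClusterComponent:
    """One component of a marker-space Gaussian mixture on log10-load scale."""

    label: str
    fraction: float
    log_mean: dict[str, float] = field(default_factory=dict)
    log_sd: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort."""

    n_lanes: int
    species: tuple[ProteinSpecies, ...]
    model: MigrationModel
    occupancy: float = 1.0
    subpopulations: tuple[Subpopulation, ...] = ()
    baseline_level: float = 0.0
    baseline_drift: float = 0.0
    noise_sd: float = 0.0
    grid_step: float = 1.0
    seed: int = 0
    cluster_spec: tuple[ClusterComponent, ...] | None = None
    # lane-wide electromigration jitter (um, SD): a common per-lane offset
    # shared by every band in the lane, as gel-to-gel and lane-to-lane field
    # variation shifts all species together (the reason an internal
    # electromigration control such as actinin is probed)
    lane_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lanes < 0:
            raise ValueError("n_lanes must be non-negative")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        fr = [s.fraction for s in self.subpopulations]
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1.0 + 1e-12:
            raise ValueError("subpopulation fractions must be in [0,1] and sum <= 1")
        if self.cluster_spec is not None:
            cf = [c.fraction for c in self.cluster_spec]
            if any(f < 0 for f in cf) or abs(sum(cf) - 1.0) > 1e-9:
                raise ValueError("cluster fractions must be non-negative and sum to 1")


def _grid(model: MigrationModel, step: float) -> np.ndarray:
    n = int(round(model.axis_length / step)) + 1
    return np.arange(n, dtype=float) * step


def gaussian_band(x: np.ndarray, load: float, center: float, sigma: float) -> np.ndarray:
    """Band profile with analytic area equal to ``load``."""
    amp = load / (sigma * _SQRT2PI)
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def simulate_profile(
    bands: list[tuple[float, float, float]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one lane trace from (load, center_um, sigma_um) bands.

    Returns (positions, intensities).  intensity(x) = sum of Gaussian
    bands + baseline_level + baseline_drift * x + N(0, noise_sd).
    """
    x = _grid(config.model, config.grid_step)
    if x.size == 0:
        raise ValueError("empty position grid")
    y = np.full_like(x, config.baseline_level) + config.baseline_drift * x
    for load, center, sigma in bands:
        if load > 0:
            y += gaussian_band(x, load, center, sigma)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        y = y + rng.normal(0.0, config.noise_sd, size=x.shape)
    return x, y


def allocate_counts(n: int, fractions: list[float]) -> list[int]:
    """Deterministic largest-remainder allocation of n items to fractions.

    Base counts are floor(f*n); leftover units go to the largest fractional
    remainders, ties broken by lower index.  Guarantees round(f*n) for a
    single planted fraction and exact totals for partitions.
    """
    raw = [f * n for f in fractions]
    base = [int(math.floor(r + 1e-9)) for r in raw]
    rem = [r - b for r, b in zip(raw, base)]
    short = int(round(sum(raw))) - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-rem[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def _draw_load(sp: ProteinSpecies, rng: np.random.Generator, noise_sd: float) -> float:
    if sp.mean_load == 0:
        return 0.0
    if sp.load_cv == 0:
        load = sp.mean_load
    else:
        mu, sig = lognormal_params(sp.mean_load, sp.load_cv)
        load = float(rng.lognormal(mu, sig))
    if sp.min_snr is not None and noise_sd > 0:
        floor = sp.min_snr * noise_sd * sp.sigma_um * _SQRT2PI
        load = max(load, floor)
    return load


def _draw_center(sp: ProteinSpecies, model: MigrationModel,
                 rng: np.random.Generator,
                 lane_offset: float = 0.0) -> tuple[float, bool]:
    c = model.distance(sp.mass_kda) + lane_offset
    if sp.center_sd_um > 0:
        jit = float(rng.normal(0.0, sp.center_sd_um))
        jit = float(np.clip(jit, -2.0 * sp.center_sd_um, 2.0 * sp.center_sd_um))
        c += jit
    if sp.center_bounds is not None:
        c = float(np.clip(c, *sp.center_bounds))
    return c, model.in_range(c)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort of lanes: (profiles long table, truth table).

    Profiles: one row per sample point per lane x target.  Truth: one row
    per lane with occupancy, subpopulation and cluster labels and the true
    per-species (load, center, sigma).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lanes
    n_occ = int(round(config.occupancy * n))
    occupied = np.zeros(n, dtype=bool)
    occupied[:n_occ] = True
    rng.shuffle(occupied)

    sub_counts = allocate_counts(n_occ, [s.fraction for s in config.subpopulations])
    sub_labels_pool = []
    for sub, cnt in zip(config.subpopulations, sub_counts):
        sub_labels_pool += [sub.label] * cnt
    sub_labels_pool += [""] * (n_occ - len(sub_labels_pool))
    sub_pool = np.array(sub_labels_pool, dtype=object)
    rng.shuffle(sub_pool)

    if config.cluster_spec is not None:
        cl_counts = allocate_counts(n_occ, [c.fraction for c in config.cluster_spec])
        cl_pool = []
        for comp, cnt in zip(config.cluster_spec, cl_counts):
            cl_pool += [comp.label] * cnt
        cl_pool_arr = np.array(cl_pool, dtype=object)
        rng.shuffle(cl_pool_arr)
        comp_by_label = {c.label: c for c in config.cluster_spec}
    else:
        cl_pool_arr = None
        comp_by_label = {}

    sub_by_label = {s.label: s for s in config.subpopulations}

    profile_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    occ_idx = 0
    for lane in range(n):
        lane_id = f"lane{lane:04d}"
        rec: dict = {"lane_id": lane_id, "has_cell": bool(occupied[lane]),
                     "subpop_label": "", "cluster_label": ""}
        bands_by_species: list[tuple[ProteinSpecies, float, float, float]] = []
        if occupied[lane]:
            sub_label = str(sub_pool[occ_idx])
            rec["subpop_label"] = sub_label
            cluster_label = ""
            comp = None
            if cl_pool_arr is not None:
                cluster_label = str(cl_pool_arr[occ_idx])
                comp = comp_by_label.get(cluster_label)
            rec["cluster_label"] = cluster_label
            occ_idx += 1

            lane_offset = 0.0
            if config.lane_jitter_sd > 0:
                lane_offset = float(np.clip(
                    rng.normal(0.0, config.lane_jitter_sd),
                    -2.0 * config.lane_jitter_sd, 2.0 * config.lane_jitter_sd))
            rec["lane_offset_um"] = lane_offset

            panel = list(config.species)
            if sub_label and sub_label in sub_by_label:
                panel += list(sub_by_label[sub_label].extra_species)
            for sp in panel:
                if comp is not None and sp.name in comp.log_mean:
                    lm = comp.log_mean[sp.name]
                    ls = comp.log_sd.get(sp.name, 0.0)
                    load = float(10.0 ** rng.normal(lm, ls))
                else:
                    load = _draw_load(sp, rng, config.noise_sd)
                center, ok = _draw_center(sp, config.model, rng, lane_offset)
                rec[f"load_{sp.name}"] = load
                rec[f"center_{sp.name}"] = center
                rec[f"sigma_{sp.name}"] = sp.sigma_um
                rec[f"inrange_{sp.name}"] = ok
                bands_by_species.append((sp, load, center, sp.sigma_um))
        else:
            occ_idx += 0

        # one physical trace per channel x probing round; species sharing a
        # trace (full-length and truncated HER2) co-migrate on it.  The trace
        # is labeled by the base-panel species of that channel/round.  Empty
        # lanes still yield baseline+noise traces for the base panel.
        trace_keys: dict[tuple[str, int], str] = {}
        for sp in config.species:
            trace_keys.setdefault((sp.channel, sp.probe_round), sp.name)
        for sp, *_ in bands_by_species:
            trace_keys.setdefault((sp.channel, sp.probe_round), sp.name)
        for (channel, probe_round), label in trace_keys.items():
            bands = [(load, c, s) for spx, load, c, s in bands_by_species
                     if spx.channel == channel and spx.probe_round == probe_round]
            x, y = simulate_profile(bands, config, rng)
            profile_rows.append(pd.DataFrame({
                "lane_id": lane_id,
                "round": probe_round,
                "channel": channel,
                "target": label,
                "position_um": x,
                "intensity_afu": y,
            }))
        truth_rows.append(rec)

    profiles = (pd.concat(profile_rows, ignore_index=True)
                if profile_rows else pd.DataFrame(
                    columns=["lane_id", "round", "channel", "target",
                             "position_um", "intensity_afu"]))
    truth = pd.DataFrame(truth_rows)
    return profiles, truth


# ---------------------------------------------------------------------------
# slide-image rendering (the scanner step, inverted)

def make_layout(lane_ids: list[str], lane_width_px: int = 6, gap_px: int = 3,
                um_per_px: float = 1.0) -> dict:
    """Row-band layout: each lane occupies lane_width_px image rows."""
    lanes = {}
    row = gap_px
    for lid in lane_ids:
        lanes[lid] = {"row_start": row, "row_stop": row + lane_width_px}
        row += lane_width_px + gap_px
    return {"um_per_px": um_per_px, "lane_width_px": lane_width_px,
            "n_rows": row, "lanes": lanes}


def render_slide_image(profiles: pd.DataFrame, layout: dict) -> np.ndarray:
    """Render lane profiles into a 16-bit grayscale slide image.

    Each lane's pixel rows replicate its intensity profile along the
    separation axis (columns).  Background pixels are zero.  Inverse of
    :func:`scwb.quant.extract_profile` up to uint16 quantization.
    """
    spans = []
    for lid, spec in layout["lanes"].items():
        spans.append((lid, spec["row_start"], spec["row_stop"]))
    spans.sort(key=lambda t: t[1])
    for (_, _, stop), (_, start, _) in zip(spans, spans[1:]):
        if start < stop:
            raise ValueError("overlapping lane bands in layout")

    um_per_px = float(layout["um_per_px"])
    max_pos = float(profiles["position_um"].max())
    n_cols = int(round(max_pos / um_per_px)) + 1
    img = np.zeros((layout["n_rows"], n_cols), dtype=np.uint16)
    for lid, grp in profiles.groupby("lane_id"):
        if lid not in layout["lanes"]:
            raise KeyError(f"lane {lid!r} missing from layout")
        spec = layout["lanes"][lid]
        cols = np.round(grp["position_um"].to_numpy() / um_per_px).astype(int)
        vals = np.clip(np.round(grp["intensity_afu"].to_numpy()), 0, 65535)
        row_slice = slice(spec["row_start"], spec["row_stop"])
        img[row_slice, cols] = vals.astype(np.uint16)[None, :]
    return img


# ---------------------------------------------------------------------------
# presets reproducing the study's cohort compositions

_CONTROL_PANEL_MASSES = {"actinin": 100.0, "GAPDH": 36.0, "panCK": 50.0}


def _terbb2_species(min_snr: float = 15.0) -> ProteinSpecies:
    return ProteinSpecies(
        name="terbb2", mass_kda=128.7, mean_load=3.0e4, load_cv=0.77,
        sigma_um=120.7 / 2.3548, channel="her2", probe_round=1,
        # marginal center SD ~18.1 um = lane-wide 15.7 (common mode with
        # p185) plus sqrt(18.1^2 - 15.7^2) ~ 9.0 um of band-specific jitter
        center_sd_um=9.0, min_snr=min_snr,
        # planted bands are detectable by construction: their centers stay
        # well interior to the 150-300 um truncated-HER2 fit window
        center_bounds=(165.0, 285.0),
    )


def _base_panel() -> tuple[ProteinSpecies, ...]:
    ctrl = []
    for name, mass in _CONTROL_PANEL_MASSES.items():
        ctrl.append(ProteinSpecies(
            name=name, mass_kda=mass, mean_load=8.0e4, load_cv=0.4,
            sigma_um=25.0, channel={"actinin": "red", "GAPDH": "green",
                                    "panCK": "red"}[name],
            probe_round={"actinin": 1, "GAPDH": 1, "panCK": 2}[name],
            center_sd_um=5.0, min_snr=8.0,
        ))
    # p185 center variation is carried entirely by the lane-wide offset
    p185 = ProteinSpecies(
        name="p185", mass_kda=185.0, mean_load=4.0e5, load_cv=0.5,
        sigma_um=93.7 / 2.3548, channel="her2", probe_round=1,
        center_sd_um=0.0, min_snr=8.0,
    )
    return tuple(ctrl + [p185])


def bt474_preset(seed: int = 0, n_lanes: int = 391,
                 terbb2_count: int = 29) -> SimulationConfig:
    """Cohort emulating the BT474 study population.

    391 occupied HER2-positive lanes, of which 29 (7.4%) carry a planted
    truncated-HER2 band at 188.2 um with amplitude SNR >= 15; every
    planted lane also carries the full-length p185 band (truncated forms
    co-occur with full-length HER2).
    """
    frac = terbb2_count / n_lanes if n_lanes else 0.0
    return SimulationConfig(
        n_lanes=n_lanes,
        species=_base_panel(),
        model=bt474_migration_model(),
        occupancy=1.0,
        subpopulations=(Subpopulation(
            label="terbb2", fraction=frac,
            extra_species=(_terbb2_species(),)),),
        baseline_level=50.0,
        baseline_drift=0.02,
        noise_sd=30.0,
        lane_jitter_sd=15.7,
        seed=seed,
    )


def tumor_preset(name: str, seed: int = 0) -> SimulationConfig:
    """Clinical-tumor presets: (HER2+ lanes, planted truncated-HER2 lanes).

    "t0903": 19 of 127 (15%); "t0909": 36 of 90 (40%).
    """
    sizes = {"t0903": (127, 19), "t0909": (90, 36)}
    if name not in sizes:
        raise KeyError(f"unknown tumor preset {name!r}")
    n, k = sizes[name]
    cfg = bt474_preset(seed=seed, n_lanes=n, terbb2_count=k)
    return cfg


def config_from_file(path, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from a JSON or YAML file.

    The file mirrors the dataclass: top-level scalars plus ``model``
    (intercept_a/slope_b/axis_length), ``species`` (list of species
    mappings) and optional ``subpopulations`` / ``cluster_spec``.
    """
    import json
    from pathlib import Path

    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)

    def _species(d: dict) -> ProteinSpecies:
        if "center_bounds" in d and d["center_bounds"] is not None:
            d = dict(d, center_bounds=tuple(d["center_bounds"]))
        return ProteinSpecies(**d)

    model = MigrationModel(**raw.pop("model"))
    species = tuple(_species(d) for d in raw.pop("species"))
    subs = tuple(
        Subpopulation(label=s["label"], fraction=s["fraction"],
                      extra_species=tuple(_species(d)
                                          for d in s.get("extra_species", ())))
        for s in raw.pop("subpopulations", ()))
    clusters = raw.pop("cluster_spec", None)
    if clusters is not None:
        clusters = tuple(ClusterComponent(**c) for c in clusters)
    if seed is not None:
        raw["seed"] = int(seed)
    return SimulationConfig(model=model, species=species,
                            subpopulations=subs, cluster_spec=clusters, **raw)


def simulate_marker_mixture(
    n_cells: int = 217,
    markers: tuple[str, ...] = ("rs6", "p-rs6", "p185", "terbb2"),
    n_components: int = 5,
    separation: float = 6.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker matrix drawn from a well-separated spherical Gaussian mixture.

    Component means are placed so every pair is >= ``separation``
    within-component SDs apart (unit SD components); cells are allocated
    to components in equal deterministic shares, then shuffled.  Returns
    (DataFrame of raw marker values, true component labels 1..k).
    """
    rng = np.random.default_rng(rng)
    d = len(markers)
    # deterministic mean placement: scaled coordinate directions and diagonals
    base = []
    i = 0
    while len(base) < n_components:
        v = np.zeros(d)
        if i < d:
            v[i] = 1.0
        else:
            j = i - d
            v[j % d] = 1.0
            v[(j + 1) % d] = 1.0
            v /= math.sqrt(2.0)
        base.append(v)
        i += 1
    means = np.array(base)
    # min pairwise distance of unit/diagonal directions is sqrt(2-sqrt(2))~0.765
    dmin = min(np.linalg.norm(a - b) for idx, a in enumerate(means)
               for b in means[idx + 1:])
    means = means * (separation / dmin)

    counts = allocate_counts(n_cells, [1.0 / n_components] * n_components)
    labels = np.repeat(np.arange(1, n_components + 1), counts)
    rng.shuffle(labels)
    X = means[labels - 1] + rng.normal(0.0, 1.0, size=(n_cells, d))
    return pd.DataFrame(X, columns=list(markers)), labels
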