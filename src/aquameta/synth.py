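"""Synthetic assay-table generator with known ground truth.

Emulates the structure of sparse aquatic-toxicity collections: a nested
phylum -> class -> species taxonomy, long-tailed assay counts per species,
binary fingerprint + continuous descriptor chemical features, duration
dependent log10 endpoints, replicate measurements, and bounded records.

Every generator is a pure function of its :class:`SynthConfig`; re-running
with the same config yields identical tables.  Ground truth (per-species
intercepts and slopes) is returned separately so parameter-recovery and
multi-task-advantage properties can be asserted downstream without the
pipeline ever reading it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_taxonomy",
    "generate_chemicals",
    "generate_assays",
    "generate_dataset",
    "write_dataset",
]

BOUND_EXACT = "exact"
BOUND_LESS = "less_than"
BOUND_GREATER = "greater_than"

HYDROPHOBICITY_COL = "pc_logkow"


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic data family.

    The target for a (species ``s``, chemical ``c``, duration ``d``) cell is

        log10(endpoint) = intercept + alpha_s + w_s * logkow_c
                          + duration_effect * log10(d) + eps,

    with ``alpha_s`` the sum of nested phylum/class/species Gaussian draws,
    ``w_s ~ Normal(slope_mean, slope_sd)`` and ``eps ~ Normal(0, sigma_noise)``.
    """

    n_phyla: int = 3
    n_classes_per_phylum: int = 2
    n_species: int = 30
    n_chemicals: int = 200
    n_fp_bits: int = 1024
    n_physchem: int = 6
    missing_rate: float = 0.1
    n_assays: int = 2000
    zipf_exponent: float = 1.0
    sigma_phylum: float = 1.0
    sigma_class: float = 0.5
    sigma_species: float = 0.25
    slope_mean: float = -0.7
    slope_sd: float = 0.1
    intercept: float = 2.0
    sigma_noise: float = 0.3
    duration_effect: float = -0.3
    sigma_replicate: float = 0.2
    replicate_rate: float = 0.05
    bound_rate: float = 0.02
    durations: tuple[float, ...] = (1.0, 2.0, 4.0, 21.0)
    fp_on_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_phyla", "n_classes_per_phylum", "n_species",
                     "n_chemicals", "n_fp_bits", "n_assays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_physchem < 1:
            raise ValueError("n_physchem must be >= 1 (hydrophobicity column)")
        for name in ("sigma_phylum", "sigma_class", "sigma_species",
                     "sigma_noise", "sigma_replicate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("replicate_rate", "bound_rate", "missing_rate", "fp_on_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if len(self.durations) == 0 or any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive and non-empty")


@dataclasses.dataclass
class GroundTruth:
    """True generating parameters, recorded per taxonomy level.

    ``alpha(species)`` decomposes exactly as the sum of the phylum, class and
    species components stored here.
    """

    intercept: float
    duration_effect: float
    sigma_noise: float
    phylum_effects: dict[str, float]
    class_effects: dict[str, float]
    species_effects: dict[str, float]
    slopes: dict[str, float]
    species_class: dict[str, str]
    species_phylum: dict[str, str]

    def alpha(self, species_id: str) -> float:
        return (
            self.phylum_effects[self.species_phylum[species_id]]
            + self.class_effects[self.species_class[species_id]]
            + self.species_effects[species_id]
        )

    def expected_target(self, species_id: str, logkow: float, duration_days: float) -> float:
        return (
            self.intercept
            + self.alpha(species_id)
            + self.slopes[species_id] * logkow
            + self.duration_effect * np.log10(duration_days)
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def generate_taxonomy(cfg: SynthConfig) -> pd.DataFrame:
    """Build a species -> class -> phylum table.

    Classes are nested in phyla.  The first ``n_classes`` species are placed
    round-robin so that every class is non-empty whenever
    ``n_species >= n_phyla * n_classes_per_phylum``; the remainder are
    assigned uniformly at random.
    """
    rng = np.random.default_rng(cfg.seed)
    phyla = [f"phylum_{p:02d}" for p in range(cfg.n_phyla)]
    classes = []
    class_phylum = {}
    for p, phylum in enumerate(phyla):
        for j in range(cfg.n_classes_per_phylum):
            name = f"class_{p:02d}_{j:02d}"
            classes.append(name)
            class_phylum[name] = phylum
    n_classes = len(classes)
    rows = []
    for i in range(cfg.n_species):
        if i < n_classes:
            cls = classes[i % n_classes]
        else:
            cls = classes[int(rng.integers(n_classes))]
        rows.append({
            "species_id": f"sp_{i:04d}",
            "class_name": cls,
            "phylum_name": class_phylum[cls],
        })
    return pd.DataFrame(rows)


def generate_chemicals(cfg: SynthConfig) -> pd.DataFrame:
    """Build the chemical feature table.

    Columns: ``chemical_id``, ``fp_0000..`` strictly binary fingerprint bits,
    ``pc_logkow`` (the hydrophobicity-role descriptor, never masked) and
    further ``pc_*`` continuous descriptors.  A ``missing_rate`` fraction of
    the maskable descriptor entries is set to NaN with a paired
    ``<col>_missing`` indicator column.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_chemicals
    data: dict[str, np.ndarray] = {
        "chemical_id": np.array([f"chem_{i:05d}" for i in range(n)], dtype=object)
    }
    fp = (rng.random((n, cfg.n_fp_bits)) < cfg.fp_on_rate).astype(np.int64)
    for j in range(cfg.n_fp_bits):
        data[f"fp_{j:04d}"] = fp[:, j]
    data[HYDROPHOBICITY_COL] = rng.normal(2.0, 1.5, size=n)
    pc_cols = []
    for j in range(1, cfg.n_physchem):
        col = f"pc_{j:02d}"
        pc_cols.append(col)
        data[col] = rng.normal(0.0, 1.0, size=n)
    frame = pd.DataFrame(data)
    # hydrophobicity stays observed: it drives the ground truth targets
    for col in pc_cols:
        mask = rng.random(n) < cfg.missing_rate
        values = frame[col].to_numpy(dtype=float)
        values[mask] = np.nan
        frame[col] = values
        frame[f"{col}_missing"] = mask.astype(np.int64)
    return frame


def _species_counts(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated-Zipf assay counts over species, renormalized to n_assays."""
    ranks = np.arange(1, cfg.n_species + 1, dtype=float)
    weights = ranks ** (-cfg.zipf_exponent)
    return rng.multinomial(cfg.n_assays, weights / weights.sum())


def generate_assays(
    cfg: SynthConfig,
    taxonomy: pd.DataFrame,
    chemicals: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate assay records and return them with their ground truth.

    Raw endpoints are ``10 ** target`` in mg/L.  A ``replicate_rate``
    fraction of cells receives 2-4 replicate rows with multiplicative
    lognormal noise on the raw endpoint; a ``bound_rate`` fraction of rows is
    flagged ``<`` / ``>`` with the value clamped to the species' 5th / 95th
    raw-endpoint percentile.
    """
    if len(taxonomy) == 0 or len(chemicals) == 0:
        raise ValueError("taxonomy and chemicals must be non-empty")
    rng = np.random.default_rng(cfg.seed + 2)

    species = taxonomy["species_id"].tolist()
    species_class = dict(zip(taxonomy["species_id"], taxonomy["class_name"]))
    species_phylum = dict(zip(taxonomy["species_id"], taxonomy["phylum_name"]))
    phyla = sorted(set(species_phylum.values()))
    classes = sorted(set(species_class.values()))

    truth = GroundTruth(
        intercept=cfg.intercept,
        duration_effect=cfg.duration_effect,
        sigma_noise=cfg.sigma_noise,
        phylum_effects={p: float(rng.normal(0.0, cfg.sigma_phylum)) for p in phyla},
        class_effects={c: float(rng.normal(0.0, cfg.sigma_class)) for c in classes},
        species_effects={s: float(rng.normal(0.0, cfg.sigma_species)) for s in species},
        slopes={s: float(rng.normal(cfg.slope_mean, cfg.slope_sd)) for s in species},
        species_class=species_class,
        species_phylum=species_phylum,
    )

    logkow = dict(zip(chemicals["chemical_id"], chemicals[HYDROPHOBICITY_COL]))
    chem_ids = chemicals["chemical_id"].to_numpy(dtype=object)
    counts = _species_counts(cfg, rng)

    rows: list[dict] = []
    for s, count in zip(species, counts):
        if count == 0:
            continue
        replace = count > len(chem_ids)
        chosen = rng.choice(chem_ids, size=count, replace=replace)
        durations = rng.choice(np.asarray(cfg.durations, dtype=float), size=count)
        noise = rng.normal(0.0, cfg.sigma_noise, size=count)
        for c, d, eps in zip(chosen, durations, noise):
            target = truth.expected_target(s, logkow[c], d) + eps
            rows.append({
                "species_id": s,
                "subspecies_id": pd.NA,
                "class_name": species_class[s],
                "phylum_name": species_phylum[s],
                "chemical_id": c,
                "duration": float(d),
                "duration_unit": "d",
                "endpoint_value": float(10.0 ** target),
                "endpoint_units": "mg/L",
                "bound": BOUND_EXACT,
            })

    # replicate a fraction of cells on the raw scale (lognormal noise)
    if cfg.replicate_rate > 0 and rows:
        extra: list[dict] = []
        for row in rows:
            if rng.random() < cfg.replicate_rate:
                for _ in range(int(rng.integers(1, 4))):  # 2-4 rows per cell total
                    rep = dict(row)
                    rep["endpoint_value"] = float(
                        row["endpoint_value"]
                        * np.exp(rng.normal(0.0, cfg.sigma_replicate))
                    )
                    extra.append(rep)
        rows.extend(extra)

    frame = pd.DataFrame(rows)
    if len(frame) == 0:
        raise ValueError("no assays generated; increase n_assays")

    if cfg.bound_rate > 0:
        values = frame["endpoint_value"].to_numpy()
        lo = frame.groupby("species_id")["endpoint_value"].transform(
            lambda v: np.percentile(v, 5.0))
        hi = frame.groupby("species_id")["endpoint_value"].transform(
            lambda v: np.percentile(v, 95.0))
        flag = rng.random(len(frame)) < cfg.bound_rate
        direction = rng.random(len(frame)) < 0.5
        bounds = frame["bound"].to_numpy(dtype=object)
        for i in np.flatnonzero(flag):
            if direction[i]:
                bounds[i] = BOUND_LESS
                values[i] = lo.iloc[i]
            else:
                bounds[i] = BOUND_GREATER
                values[i] = hi.iloc[i]
        frame["bound"] = bounds
        frame["endpoint_value"] = values

    frame.insert(0, "assay_id", [f"assay_{i:06d}" for i in range(len(frame))])
    return frame.reset_index(drop=True), truth


def generate_dataset(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: (assays, chemicals, taxonomy, truth)."""
    taxonomy = generate_taxonomy(cfg)
    chemicals = generate_chemicals(cfg)
    assays, truth = generate_assays(cfg, taxonomy, chemicals)
    return assays, chemicals, taxonomy, truth


def write_dataset(
    out_dir: str | Path,
    assays: pd.DataFrame,
    chemicals: pd.DataFrame,
    taxonomy: pd.DataFrame,
    truth: GroundTruth | None = None,
    parquet: bool = False,
) -> dict[str, Path]:
    """Write tables as UTF-8 CSV ("." decimal separator); truth as a JSON sidecar.

    The sidecar is never read by the modelling pipeline.  ``parquet=True``
    additionally writes columnar copies next to the CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("assays", assays), ("chemicals", chemicals), ("taxonomy", taxonomy)):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
        if parquet:
            frame.to_parquet(out / f"{name}.parquet")
    if truth is not None:
        path = out / "ground_truth.json"
        path.write_text(truth.to_json())
        paths["ground_truth"] = path
    return paths
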