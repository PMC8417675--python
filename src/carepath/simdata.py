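"""Seeded synthetic study generator.

Produces a complete synthetic obstetric cohort with the statistical
structure the downstream analysis assumes: patients with demographics and
home locations, trimester-stamped coded event sequences driven by
cluster-specific first-order Markov chains, spatial layers (transit, traffic,
parcels, green space, sidewalks) over a planar region, census-tract
attributes, and a binary postpartum-depression (PPD) outcome generated from
latent cluster membership with configurable odds ratios.

Every table/layer draws from its own random stream split deterministically
from the master seed, so adding a layer does not perturb other outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "SimBundle",
    "default_vocab",
    "default_transition_matrices",
    "generate_cohort",
    "generate_event_sequences",
    "generate_spatial_region",
    "generate_outcomes",
    "simulate_study",
    "write_bundle",
]

PPD_CODE = "DX_PPD"
ED_CODE = "ENC_ED"

#: Event-token vocabulary; the prefix encodes the event type
#: (ENC=encounter, DX=diagnosis with SNOMED-like role, MED=ATC-class-like).
DEFAULT_VOCAB: dict[str, list[str]] = {
    "encounter": ["ENC_PRENATAL", "ENC_ULTRASOUND", ED_CODE],
    "diagnosis": [
        "DX_HYPOTHYROID",
        "DX_THREAT_MISC",
        "DX_ABD_PAIN",
        "DX_ANXIETY",
        "DX_HIGHRISK",
        "DX_GLUCOSE_ABN",
        "DX_UNPLANNED",
        "DX_MOOD",
    ],
    "medication": [
        "MED_OPIOID",
        "MED_ANALGESIC",
        "MED_PROGESTOGEN",
        "MED_THYROID",
        "MED_ANTIEMETIC",
        "MED_VITAMIN",
    ],
}

# Cluster-specific emphasis vocabularies: cluster 1 = complicated /
# high-utilization pregnancies, cluster 2 = intermediate, cluster 3 = routine
# care.  Ordered lists: the chain tends to walk along each list, planting
# recurrent sequential motifs for the pattern miner.
DEFAULT_EMPHASIS: list[list[str]] = [
    ["DX_ANXIETY", "DX_MOOD", "DX_HIGHRISK", "DX_THREAT_MISC", "MED_OPIOID", "MED_THYROID", ED_CODE],
    ["ENC_PRENATAL", "DX_ABD_PAIN", "DX_GLUCOSE_ABN", "DX_HYPOTHYROID", "MED_ANALGESIC", "MED_ANTIEMETIC"],
    ["ENC_PRENATAL", "ENC_ULTRASOUND", "MED_VITAMIN", "MED_PROGESTOGEN", "DX_UNPLANNED"],
]

DEFAULT_LAYER_INTENSITIES: dict[str, dict] = {
    # per_km2 for point layers; n_features for line/polygon layers.
    # x_gradient in [0, 1): density tilt along x (0 = homogeneous).
    "bus_stops": {"per_km2": 40.0, "x_gradient": 0.6},
    "subway_stations": {"per_km2": 3.0, "x_gradient": 0.6},
    "intersections": {"per_km2": 50.0, "x_gradient": 0.4},
    "bike_paths": {"n_features": 60, "x_gradient": 0.5},
    "traffic": {"n_features": 80, "x_gradient": 0.0},
    "green_spaces": {"n_features": 25, "x_gradient": 0.0},
    "sidewalks": {"n_features": 120, "x_gradient": 0.5},
    "parcel_cell_m": {"size": 200.0},
}

LANDUSE_CLASSES = ["residential", "commercial", "retail", "industrial", "recreation", "other"]


class ConfigurationError(ValueError):
    """Raised when a SimConfig (or run configuration) is invalid."""


def _flat_vocab(vocab: dict[str, list[str]]) -> list[str]:
    return [t for toks in vocab.values() for t in toks]


def default_transition_matrices(
    vocab: dict[str, list[str]] | None = None,
    emphasis: list[list[str]] | None = None,
    boost: float = 8.0,
    follow_prob: float = 0.5,
) -> list[np.ndarray]:
    """Build per-cluster first-order transition matrices over the vocabulary.

    Each cluster has a stationary preference that up-weights its emphasis
    tokens by ``boost``; from an emphasis token the chain moves to the next
    emphasis token with probability ``follow_prob`` (planting ordered motifs)
    and otherwise resamples from the stationary preference.
    """
    vocab = vocab or DEFAULT_VOCAB
    emphasis = emphasis if emphasis is not None else DEFAULT_EMPHASIS
    tokens = _flat_vocab(vocab)
    idx = {t: i for i, t in enumerate(tokens)}
    v = len(tokens)
    mats = []
    for emph in emphasis:
        w = np.ones(v)
        for t in emph:
            w[idx[t]] = boost
        pi = w / w.sum()
        m = np.tile(pi, (v, 1))
        for j, t in enumerate(emph):
            nxt = emph[(j + 1) % len(emph)]
            row = (1.0 - follow_prob) * pi
            row[idx[nxt]] += follow_prob
            m[idx[t]] = row
        mats.append(m)
    return mats


@dataclass
class SimConfig:
    """Configuration of a synthetic study.

    Defaults plant the study conditions of the emulated analysis: a
    three-cluster cohort with mixing proportions echoing the reported
    1,934 / 4,129 / 2,886 split, a baseline PPD risk of 1.14 % in the
    routine-care cluster, and cluster odds ratios of 6.3 and 2.43.
    """

    n_patients: int = 2000
    mixing_proportions: tuple[float, ...] = (0.22, 0.46, 0.32)
    vocab: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_VOCAB.items()})
    transition_specs: list[np.ndarray] | None = None
    emphasis: list[list[str]] = field(default_factory=lambda: [list(e) for e in DEFAULT_EMPHASIS])
    emphasis_boost: float = 8.0
    follow_prob: float = 0.5
    length_mean: float = 14.0
    region_side: float = 6000.0
    tract_size: float = 1000.0
    layer_intensities: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LAYER_INTENSITIES.items()}
    )
    # cluster-specific mean home x-position (fraction of region_side) and sd
    # in meters: ties cluster membership to the built-environment gradient.
    env_shift: tuple[float, ...] = (0.25, 0.5, 0.75)
    home_sd: float = 1200.0
    outcome_or: tuple[float, float] = (6.3, 2.43)
    baseline_ppd: float = 0.0114
    # mean pre-/post-delivery ED visit counts per cluster
    ed_pre_mean: tuple[float, ...] = (1.12, 0.68, 0.56)
    ed_post_mean: tuple[float, ...] = (0.10, 0.06, 0.05)
    frac_missing_home: float = 0.01
    frac_out_of_window: float = 0.01
    frac_age_outlier: float = 0.02
    bmi_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.mixing_proportions, dtype=float)
        if p.ndim != 1 or len(p) == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixing_proportions must be non-negative and sum to 1")
        if self.transition_specs is None:
            self.transition_specs = default_transition_matrices(
                self.vocab, self.emphasis, self.emphasis_boost, self.follow_prob
            )
        if len(self.transition_specs) != len(p):
            raise ConfigurationError("one transition matrix required per mixture component")
        v = len(_flat_vocab(self.vocab))
        for m in self.transition_specs:
            m = np.asarray(m, dtype=float)
            if m.shape != (v, v) or np.any(m < 0) or np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
                raise ConfigurationError("each transition matrix row must be a probability vector over the vocabulary")
        if any(r <= 0 for r in self.outcome_or):
            raise ConfigurationError("outcome odds ratios must be positive")
        if not (0.0 < self.baseline_ppd < 1.0):
            raise ConfigurationError("baseline_ppd must lie in (0, 1)")
        if self.region_side <= 1000:
            raise ConfigurationError("region_side must exceed 1000 m so 500 m buffers fit")
        if self.length_mean < 0:
            raise ConfigurationError("length_mean must be non-negative")
        for name, spec in self.layer_intensities.items():
            for key in ("per_km2", "n_features"):
                if key in spec and spec[key] < 0:
                    raise ConfigurationError(f"negative intensity for layer {name!r}")

    @property
    def k_true(self) -> int:
        return len(self.mixing_proportions)

    @property
    def tokens(self) -> list[str]:
        return _flat_vocab(self.vocab)

    def rng(self, stream: str) -> np.random.Generator:
        """Named random stream split deterministically from the master seed."""
        key = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence(entropy=(int(self.seed) & 0x7FFFFFFF, key)))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("mixing_proportions", "outcome_or", "env_shift", "ed_pre_mean", "ed_post_mean"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _event_type(code: str) -> str:
    if code.startswith("ENC"):
        return "encounter"
    if code.startswith("DX"):
        return "diagnosis"
    return "medication"


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the patient table and latent truth labels.

    Ages are drawn so that most fall in 18-45 with a small out-of-range
    mass to exercise the exclusion filter; home coordinates follow
    cluster-specific Gaussians over the region's x-gradient.
    """
    n = config.n_patients
    rng = config.rng("cohort")
    clusters = rng.choice(config.k_true, size=n, p=np.asarray(config.mixing_proportions)) + 1

    age = rng.normal(33.7, 4.6, size=n)
    outlier = rng.random(n) < config.frac_age_outlier
    age[outlier] = rng.uniform(15.0, 49.0, size=int(outlier.sum()))
    bmi = np.clip(rng.normal(23.8, 4.3, size=n), 15.0, 55.0)
    bmi[rng.random(n) < config.bmi_missing_rate] = np.nan
    gw = np.clip(rng.normal(38.7, 2.1, size=n), 25.0, 43.0)
    marital = np.where(rng.random(n) < 0.8667, "married", "single")
    race = rng.choice(
        ["White", "Asian", "Black", "Other", "Unknown"],
        size=n,
        p=[0.4927, 0.1887, 0.0626, 0.1091, 0.1469],
    )
    insurance = rng.choice(["Commercial", "Medicaid", "Other"], size=n, p=[0.8402, 0.1370, 0.0228])
    delivery = pd.Timestamp("2015-01-01") + pd.to_timedelta(rng.integers(0, 3 * 365, size=n), unit="D")

    means = np.asarray(config.env_shift) * config.region_side
    hx = np.clip(rng.normal(means[clusters - 1], config.home_sd), 0.0, config.region_side - 1e-6)
    hy = np.clip(rng.normal(config.region_side / 2, config.region_side / 4, size=n), 0.0, config.region_side - 1e-6)
    missing = rng.random(n) < config.frac_missing_home
    hx[missing] = np.nan
    hy[missing] = np.nan

    nt = int(np.ceil(config.region_side / config.tract_size))
    col = np.floor(np.nan_to_num(hx, nan=0.0) / config.tract_size).astype(int).clip(0, nt - 1)
    row = np.floor(np.nan_to_num(hy, nan=0.0) / config.tract_size).astype(int).clip(0, nt - 1)
    tract = np.array([f"T{r}_{c}" for r, c in zip(row, col)], dtype=object)
    tract[missing] = None

    width = len(str(n))
    pid = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)], dtype=object)
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "gestational_week": np.round(gw, 1),
            "marital": marital,
            "race": race,
            "insurance": insurance,
            "delivery_date": delivery.strftime("%Y-%m-%d"),
            "home_x": hx,
            "home_y": hy,
            "tract_id": tract,
        }
    )
    truth = pd.DataFrame({"patient_id": pid, "latent_cluster": clusters})
    return patients, truth


def generate_outcomes(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """PPD ~ Bernoulli(expit(logit(baseline) + ln(OR_c) for cluster c)).

    The last mixture component is the reference cluster; ``outcome_or``
    supplies one odds ratio per non-reference cluster, in order.
    """
    rng = config.rng("outcomes")
    beta0 = np.log(config.baseline_ppd / (1.0 - config.baseline_ppd))
    log_or = np.concatenate([np.log(np.asarray(config.outcome_or, dtype=float)), [0.0]])
    if len(log_or) != config.k_true:
        raise ConfigurationError("outcome_or must have one entry per non-reference cluster")
    eta = beta0 + log_or[truth["latent_cluster"].to_numpy() - 1]
    p = 1.0 / (1.0 + np.exp(-eta))
    ppd = rng.random(len(truth)) < p
    return pd.DataFrame({"patient_id": truth["patient_id"], "ppd": ppd})


def _draw_days(rng: np.random.Generator, lo: int, hi: int, k: int, used: set[int]) -> list[int]:
    """k distinct integer days in [lo, hi] avoiding `used` (timestamps must strictly increase)."""
    avail = hi - lo + 1 - len([d for d in used if lo <= d <= hi])
    k = min(k, max(avail, 0))
    days: list[int] = []
    while len(days) < k:
        d = int(rng.integers(lo, hi + 1))
        if d not in used:
            used.add(d)
            days.append(d)
    return days


def generate_event_sequences(
    config: SimConfig,
    patients: pd.DataFrame,
    truth: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-patient ordered event rows from the cluster-specific Markov chain.

    Sequence length is shifted Poisson (1 + Poisson(length_mean - 1), so
    every patient has at least one event); prenatal chain events live in
    [-7*gestational_week, 0], ED encounters are added pre/post delivery, and
    PPD-positive patients receive a depression diagnosis in (0, 365].
    A configurable sliver of patients has all events pushed outside the
    study encounter window to exercise the exclusion filter.
    """
    rng = config.rng("events")
    tokens = config.tokens
    tok_idx = {t: i for i, t in enumerate(tokens)}
    mats = [np.asarray(m, dtype=float) for m in config.transition_specs]
    pis = [m[0].copy() for m in mats]
    # stationary start distribution: use the emphasis-weighted row of a
    # non-emphasis token (all such rows equal the stationary preference)
    for c, m in enumerate(mats):
        emph_idx = {tok_idx[t] for t in config.emphasis[c] if t in tok_idx} if c < len(config.emphasis) else set()
        for j in range(len(tokens)):
            if j not in emph_idx:
                pis[c] = m[j].copy()
                break
    label = dict(zip(truth["patient_id"], truth["latent_cluster"]))
    ppd = dict(zip(outcomes["patient_id"], outcomes["ppd"])) if outcomes is not None else {}

    rows: list[tuple[str, int, str, str]] = []
    for pid, gwk in zip(patients["patient_id"], patients["gestational_week"]):
        c = label.get(pid)
        if c is None or not (1 <= c <= len(mats)):
            raise ConfigurationError(f"unknown cluster label for patient {pid!r}")
        m, pi = mats[c - 1], pis[c - 1]
        length = 1 + int(rng.poisson(max(config.length_mean - 1.0, 0.0)))
        start_day = -int(round(7 * float(gwk)))
        used: set[int] = set()
        out_of_window = rng.random() < config.frac_out_of_window
        if out_of_window:
            lo, hi = -730, start_day - 366
            if hi < lo:
                hi = lo
        else:
            lo, hi = start_day, 0
        days = sorted(_draw_days(rng, lo, hi, length, used))
        state = int(rng.choice(len(tokens), p=pi))
        seq = [tokens[state]]
        for _ in range(len(days) - 1):
            state = int(rng.choice(len(tokens), p=m[state]))
            seq.append(tokens[state])
        rows.extend((pid, d, _event_type(t), t) for d, t in zip(days, seq))
        if not out_of_window:
            n_pre = int(rng.poisson(config.ed_pre_mean[c - 1]))
            n_post = int(rng.poisson(config.ed_post_mean[c - 1]))
            rows.extend((pid, d, "encounter", ED_CODE) for d in _draw_days(rng, -365, -1, n_pre, used))
            rows.extend((pid, d, "encounter", ED_CODE) for d in _draw_days(rng, 1, 365, n_post, used))
            if ppd.get(pid, False):
                rows.extend((pid, d, "diagnosis", PPD_CODE) for d in _draw_days(rng, 1, 365, 1, used))
    events = pd.DataFrame(rows, columns=["patient_id", "t", "event_type", "code"])
    return events.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# spatial region


def _tilted_x(rng: np.random.Generator, n: int, side: float, g: float) -> np.ndarray:
    """x-coordinates with linear density 1 + g*(2x/side - 1), mean preserved."""
    u = rng.random(n)
    if abs(g) < 1e-12:
        return u * side
    # inverse CDF of the linear density on [0, 1]
    a = 1.0 - g
    x01 = (-a + np.sqrt(a * a + 4.0 * g * u)) / (2.0 * g)
    return x01 * side


def _point_layer(rng: np.random.Generator, side: float, spec: dict) -> list[dict]:
    lam = float(spec.get("per_km2", 0.0))
    g = float(spec.get("x_gradient", 0.0))
    area_km2 = (side / 1000.0) ** 2
    n = rng.poisson(lam * area_km2)
    xs = _tilted_x(rng, n, side, g)
    ys = rng.random(n) * side
    return [
        {"type": "Feature", "geometry": {"type": "Point", "coordinates": [float(x), float(y)]}, "properties": {}}
        for x, y in zip(xs, ys)
    ]


def _segment_layer(rng: np.random.Generator, side: float, spec: dict, props_fn=None) -> list[dict]:
    n = int(spec.get("n_features", 0))
    g = float(spec.get("x_gradient", 0.0))
    xs = _tilted_x(rng, n, side, g)
    ys = rng.random(n) * side
    feats = []
    for x, y in zip(xs, ys):
        length = rng.uniform(200.0, 800.0)
        theta = rng.uniform(0.0, np.pi)
        dx, dy = length * np.cos(theta), length * np.sin(theta)
        x2 = float(np.clip(x + dx, 0.0, side))
        y2 = float(np.clip(y + dy, 0.0, side))
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [[float(x), float(y)], [x2, y2]]},
                "properties": props_fn(rng) if props_fn else {},
            }
        )
    return feats


def _rect(x: float, y: float, w: float, h: float) -> dict:
    return {
        "type": "Polygon",
        "coordinates": [[[x, y], [x + w, y], [x + w, y + h], [x, y + h], [x, y]]],
    }


def generate_spatial_region(config: SimConfig) -> tuple[dict[str, dict], pd.DataFrame]:
    """Generate GeoJSON-style spatial layers and the census-tract table.

    Point layers are (optionally x-tilted) Poisson processes; parcels tile
    the region with square cells whose land-use mix shifts along x from
    residential/industrial to commercial/retail, so walkability indicators
    carry a gradient that the cluster-specific home placement can load on.
    All geometry is planar, in meters.
    """
    side = config.region_side
    li = config.layer_intensities
    layers: dict[str, list[dict]] = {}
    for name in ("bus_stops", "subway_stations", "intersections"):
        layers[name] = _point_layer(config.rng(f"layer:{name}"), side, li.get(name, {}))
    layers["bike_paths"] = _segment_layer(config.rng("layer:bike_paths"), side, li.get("bike_paths", {}))
    layers["traffic"] = _segment_layer(
        config.rng("layer:traffic"),
        side,
        li.get("traffic", {}),
        props_fn=lambda r: {
            "vol_light": float(np.round(r.uniform(2000.0, 30000.0), 1)),
            "vol_heavy": float(np.round(r.uniform(200.0, 3000.0), 1)),
        },
    )

    rng = config.rng("layer:parcels")
    cell = float(li.get("parcel_cell_m", {}).get("size", 200.0))
    ncell = int(np.floor(side / cell))
    feats = []
    for i in range(ncell):
        for j in range(ncell):
            x, y = i * cell, j * cell
            xn = (x + cell / 2) / side  # 0 -> industrial/residential side, 1 -> commercial/retail
            p = np.array(
                [
                    0.55 - 0.30 * xn,  # residential
                    0.05 + 0.25 * xn,  # commercial
                    0.03 + 0.22 * xn,  # retail
                    0.25 - 0.20 * xn,  # industrial
                    0.06,  # recreation
                    0.06,  # other
                ]
            )
            p = np.clip(p, 0.005, None)
            p /= p.sum()
            cls = LANDUSE_CLASSES[int(rng.choice(len(LANDUSE_CLASSES), p=p))]
            area = cell * cell
            props = {"landuse_class": cls, "parcel_area_m2": area}
            if cls == "retail":
                props["floor_area_m2"] = float(np.round(area * rng.uniform(0.5, 3.0), 1))
            feats.append({"type": "Feature", "geometry": _rect(x, y, cell, cell), "properties": props})
    layers["parcels"] = feats

    rng = config.rng("layer:green_spaces")
    n = int(li.get("green_spaces", {}).get("n_features", 0))
    layers["green_spaces"] = [
        {
            "type": "Feature",
            "geometry": _rect(
                float(rng.uniform(0, side - 400)), float(rng.uniform(0, side - 400)),
                float(rng.uniform(100, 400)), float(rng.uniform(100, 400)),
            ),
            "properties": {},
        }
        for _ in range(n)
    ]

    rng = config.rng("layer:sidewalks")
    spec = li.get("sidewalks", {})
    n = int(spec.get("n_features", 0))
    xs = _tilted_x(rng, n, side, float(spec.get("x_gradient", 0.0)))
    feats = []
    for x in xs:
        y = float(rng.uniform(0, side - 300))
        if rng.random() < 0.5:
            feats.append({"type": "Feature", "geometry": _rect(float(x), y, float(rng.uniform(100, 300)), 3.0), "properties": {}})
        else:
            feats.append({"type": "Feature", "geometry": _rect(float(x), y, 3.0, float(rng.uniform(100, 300))), "properties": {}})
    layers["sidewalks"] = feats

    rng = config.rng("tracts")
    nt = int(np.ceil(side / config.tract_size))
    rows = []
    for r in range(nt):
        for c in range(nt):
            xn = (c + 0.5) / nt
            rows.append(
                {
                    "tract_id": f"T{r}_{c}",
                    "pm25": round(9.3 + 0.9 * xn + rng.normal(0, 0.15), 3),
                    "o3": round(46.6 - 0.8 * xn + rng.normal(0, 0.15), 3),
                    "gini": round(float(np.clip(0.50 - 0.12 * xn + rng.normal(0, 0.03), 0.2, 0.7)), 4),
                    "college_pct": round(float(np.clip(22.0 + 28.0 * xn + rng.normal(0, 4.0), 0, 100)), 2),
                    "poverty": round(float(np.clip(2.6 - 1.8 * xn + rng.normal(0, 0.4), 0, 100)), 2),
                    "uninsured_pct": round(float(np.clip(11.0 - 5.0 * xn + rng.normal(0, 1.5), 0, 100)), 2),
                    "low_food_access": int(rng.random() < 0.05),
                }
            )
    tracts = pd.DataFrame(rows)
    collections = {name: {"type": "FeatureCollection", "features": f} for name, f in layers.items()}
    return collections, tracts


@dataclass
class SimBundle:
    """A complete synthetic study."""

    config: SimConfig
    patients: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    outcomes: pd.DataFrame
    layers: dict[str, dict]
    tracts: pd.DataFrame


def simulate_study(config: SimConfig) -> SimBundle:
    """Run every generator and assemble the full synthetic bundle."""
    patients, truth = generate_cohort(config)
    outcomes = generate_outcomes(config, truth)
    events = generate_event_sequences(config, patients, truth, outcomes)
    layers, tracts = generate_spatial_region(config)
    return SimBundle(config, patients, events, truth, outcomes, layers, tracts)


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.patients.to_csv(out / "patients.csv", index=False)
    bundle.events.to_csv(out / "events.csv", index=False)
    bundle.truth.to_csv(out / "truth.csv", index=False)
    bundle.outcomes.to_csv(out / "outcomes_truth.csv", index=False)
    bundle.tracts.to_csv(out / "tracts.csv", index=False)
    layers_dir = out / "layers"
    layers_dir.mkdir(exist_ok=True)
    for name, fc in bundle.layers.items():
        with open(layers_dir / f"{name}.geojson", "w") as fh:
            json.dump(fc, fh)
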