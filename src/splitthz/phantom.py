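"""Synthetic THz-like hyperspectral tissue phantoms.

Real terahertz reflectance cubes of excised breast-conserving-surgery
specimens are not publicly deposited, so every downstream stage of the
pipeline is exercised on phantoms: spatially contiguous cancer / muscle /
fat regions on a background, class-conditional spectral signatures with
additive isotropic Gaussian noise, and an FFPE-style corruption process
that adds a systematic spectral shift to a fraction of labeled pixels
(emulating the fresh-vs-fixed tissue mismatch that motivates reliability
filtering of training data).

Conventions: 0-based (row, col, band) axis order; label codes
0=background, 1=fat, 2=muscle, 3=cancer; the ordinal class order used by
the classifier is fat < muscle < cancer.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError, LayoutError

LABEL_CODES = {"background": 0, "fat": 1, "muscle": 2, "cancer": 3}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}
#: Ordinal class order used throughout the classifier stack (label codes).
CLASS_ORDER = ("fat", "muscle", "cancer")
CLASS_CODES = tuple(LABEL_CODES[c] for c in CLASS_ORDER)  # (1, 2, 3)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [row0, row0+n_rows) x [col0, col0+n_cols)."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def mask(self, height: int, width: int) -> np.ndarray:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("rectangle must have positive extent")
        if self.row0 < 0 or self.col0 < 0 or self.row0 + self.n_rows > height or self.col0 + self.n_cols > width:
            raise LayoutError(f"rectangle {self} exceeds image bounds {height}x{width}")
        m = np.zeros((height, width), dtype=bool)
        m[self.row0 : self.row0 + self.n_rows, self.col0 : self.col0 + self.n_cols] = True
        return m


@dataclass(frozen=True)
class Disc:
    """Disc of given radius centred at (row, col); membership is r^2 <= radius^2."""

    row: float
    col: float
    radius: float

    def mask(self, height: int, width: int) -> np.ndarray:
        if self.radius <= 0:
            raise ConfigError("disc radius must be positive")
        rr, cc = np.mgrid[0:height, 0:width]
        return (rr - self.row) ** 2 + (cc - self.col) ** 2 <= self.radius**2


@dataclass
class PhantomConfig:
    """Geometry, spectra and noise levels of a synthetic phantom.

    ``class_means`` maps label name -> length-``n_bands`` mean spectrum
    (arbitrary reflectance units); ``class_noise_sd`` maps label name ->
    isotropic per-band noise standard deviation.
    """

    height: int
    width: int
    n_bands: int
    region_layout: list[tuple[Rect | Disc, str]]
    class_means: dict[str, np.ndarray]
    class_noise_sd: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1 or self.n_bands < 1:
            raise ConfigError("height, width and n_bands must all be >= 1")
        for _, label in self.region_layout:
            if label not in LABEL_CODES or label == "background":
                raise ConfigError(f"region label {label!r} not in {sorted(LABEL_CODES)}")
        for label in set(lab for _, lab in self.region_layout) | {"background"}:
            if label not in self.class_means:
                raise ConfigError(f"missing mean spectrum for class {label!r}")
            mean = np.asarray(self.class_means[label], dtype=float)
            if mean.shape != (self.n_bands,):
                raise ConfigError(f"mean spectrum for {label!r} has shape {mean.shape}, expected ({self.n_bands},)")
            if label not in self.class_noise_sd or self.class_noise_sd[label] <= 0:
                raise ConfigError(f"class {label!r} needs a positive noise SD")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["region_layout"] = [
            {"shape": type(shape).__name__, **dataclasses.asdict(shape), "label": label}
            for shape, label in self.region_layout
        ]
        d["class_means"] = {k: np.asarray(v, dtype=float).tolist() for k, v in self.class_means.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomConfig":
        d = json.loads(text)
        shapes = {"Rect": Rect, "Disc": Disc}
        layout = []
        for entry in d["region_layout"]:
            entry = dict(entry)
            label = entry.pop("label")
            shape_cls = shapes[entry.pop("shape")]
            layout.append((shape_cls(**entry), label))
        return cls(
            height=d["height"],
            width=d["width"],
            n_bands=d["n_bands"],
            region_layout=layout,
            class_means={k: np.asarray(v, dtype=float) for k, v in d["class_means"].items()},
            class_noise_sd={k: float(v) for k, v in d["class_noise_sd"].items()},
            seed=int(d["seed"]),
        )


@dataclass
class Phantom:
    """A labeled hyperspectral cube plus its corruption bookkeeping.

    ``cube`` is H x W x B reflectance, ``labels`` the H x W label-code map
    and ``corruption_mask`` flags pixels whose spectrum received the
    FFPE-style shift.
    """

    cube: np.ndarray
    labels: np.ndarray
    corruption_mask: np.ndarray
    config: PhantomConfig | None = None

    def __post_init__(self) -> None:
        if self.cube.shape[:2] != self.labels.shape or self.labels.shape != self.corruption_mask.shape:
            raise DimensionError("cube, labels and corruption_mask must share the H x W grid")
        bad = set(np.unique(self.labels)) - set(CODE_LABELS)
        if bad:
            raise LayoutError(f"label map contains unknown codes {sorted(bad)}")

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]

    def copy(self) -> "Phantom":
        return Phantom(self.cube.copy(), self.labels.copy(), self.corruption_mask.copy(), self.config)


@dataclass
class PixelDataset:
    """Flattened per-pixel view of a phantom: the unit flowing through the pipeline.

    Rows are in row-major (row, col) order; ``X`` holds band intensities.
    """

    X: np.ndarray
    y: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    corrupted: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"band_{b}" for b in range(self.n_features)])
        df.insert(0, "row", self.rows)
        df.insert(1, "col", self.cols)
        df["label"] = self.y
        df["corrupted"] = self.corrupted.astype(np.uint8)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PixelDataset":
        bands = [c for c in df.columns if c.startswith("band_")]
        return cls(
            X=df[bands].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            rows=df["row"].to_numpy(dtype=int),
            cols=df["col"].to_numpy(dtype=int),
            corrupted=df["corrupted"].to_numpy(dtype=bool),
        )


def spectral_direction(n_bands: int) -> np.ndarray:
    """Unit vector along which tissue classes are ordered in band space.

    A smooth half-sine profile: the contrast between tissue classes is
    spread over all bands but weighted toward the middle of the spectrum,
    loosely emulating a broad water-absorption contrast.
    """
    u = np.sin(np.pi * (np.arange(n_bands) + 0.5) / n_bands)
    return u / np.linalg.norm(u)


def default_class_means(
    n_bands: int, separation: float = 5.0, noise_sd: float = 1.0
) -> dict[str, np.ndarray]:
    """Class mean spectra with adjacent classes `separation * noise_sd` apart.

    All classes share a smooth base spectrum and differ by offsets along a
    common unit direction, so the Euclidean distance in band space between
    fat and muscle (and muscle and cancer) is exactly ``separation *
    noise_sd``.  The collinear geometry makes a single latent index a
    sufficient statistic, which is what an ordinal classification head
    assumes.
    """
    b = np.arange(n_bands)
    base = 10.0 + 2.0 * np.exp(-(((b - n_bands / 2) / (0.35 * n_bands + 1e-9)) ** 2))
    u = spectral_direction(n_bands)
    step = separation * noise_sd
    return {
        "background": base - 2.0 * step * u,
        "fat": base,
        "muscle": base + step * u,
        "cancer": base + 2.0 * step * u,
    }


def default_config(
    height: int = 64,
    width: int = 64,
    n_bands: int = 16,
    separation: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 7,
) -> PhantomConfig:
    """The stock phantom: a cancer disc plus muscle and fat rectangles on background."""
    h, w = height, width
    layout: list[tuple[Rect | Disc, str]] = [
        (Disc(row=0.3 * h, col=0.28 * w, radius=0.16 * min(h, w)), "cancer"),
        (Rect(row0=int(0.55 * h), col0=int(0.12 * w), n_rows=max(1, int(0.3 * h)), n_cols=max(1, int(0.3 * w))), "muscle"),
        (Rect(row0=int(0.12 * h), col0=int(0.58 * w), n_rows=max(1, int(0.3 * h)), n_cols=max(1, int(0.3 * w))), "fat"),
    ]
    return PhantomConfig(
        height=h,
        width=w,
        n_bands=n_bands,
        region_layout=layout,
        class_means=default_class_means(n_bands, separation, noise_sd),
        class_noise_sd={k: noise_sd for k in LABEL_CODES},
        seed=seed,
    )


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Sample a phantom from its config; deterministic given ``config.seed``.

    Each pixel's spectrum is drawn i.i.d. from an isotropic Gaussian around
    its class mean.  Overlapping regions raise :class:`LayoutError`.
    """
    h, w, nb = config.height, config.width, config.n_bands
    labels = np.zeros((h, w), dtype=np.int8)
    for shape, label in config.region_layout:
        m = shape.mask(h, w)
        if np.any(labels[m] != 0):
            raise LayoutError(f"region {shape} ({label}) overlaps an earlier region")
        labels[m] = LABEL_CODES[label]

    rng = np.random.default_rng(config.seed)
    cube = np.empty((h, w, nb), dtype=float)
    # fixed class iteration order keeps the draw sequence reproducible
    for name, code in sorted(LABEL_CODES.items(), key=lambda kv: kv[1]):
        m = labels == code
        n_pix = int(m.sum())
        if n_pix == 0:
            continue
        mean = np.asarray(config.class_means[name], dtype=float)
        sd = config.class_noise_sd[name]
        cube[m] = mean + sd * rng.standard_normal((n_pix, nb))
    return Phantom(cube, labels, np.zeros((h, w), dtype=bool), config)


def corrupt_labels(phantom: Phantom, fraction: float, shift: np.ndarray, seed: int = 0) -> Phantom:
    """Add a constant spectral ``shift`` to ``round(fraction * n_labeled)`` pixels.

    The label map is unchanged — corruption degrades spectra, not labels —
    and affected pixels are flagged in ``corruption_mask``.  Emulates the
    systematic fresh-vs-FFPE spectral offset in a training set.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"fraction must lie in [0, 1], got {fraction}")
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (phantom.n_bands,):
        raise DimensionError(f"shift has shape {shift.shape}, expected ({phantom.n_bands},)")

    out = phantom.copy()
    labeled = np.argwhere(phantom.labels > 0)  # row-major order
    n_flag = int(round(fraction * len(labeled)))
    if n_flag == 0:
        return out
    # draw from not-yet-flagged pixels so repeated passes hit disjoint subsets
    fresh = np.argwhere((phantom.labels > 0) & ~phantom.corruption_mask)
    if n_flag > len(fresh):
        raise ConfigError(
            f"cannot corrupt {n_flag} pixels: only {len(fresh)} labeled pixels are still clean"
        )
    rng = np.random.default_rng(seed)
    picked = fresh[rng.choice(len(fresh), size=n_flag, replace=False)]
    out.cube[picked[:, 0], picked[:, 1], :] += shift
    out.corruption_mask[picked[:, 0], picked[:, 1]] = True
    return out


def to_pixel_table(phantom: Phantom, include_background: bool = False) -> PixelDataset:
    """Flatten a phantom to one row per pixel, row-major over (row, col)."""
    h, w = phantom.labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    keep = np.ones((h, w), dtype=bool) if include_background else phantom.labels > 0
    if not keep.any():
        warnings.warn("pixel table is empty (no labeled pixels selected)", stacklevel=2)
    return PixelDataset(
        X=phantom.cube[keep].reshape(-1, phantom.n_bands).astype(float),
        y=phantom.labels[keep].astype(int),
        rows=rr[keep],
        cols=cc[keep],
        corrupted=phantom.corruption_mask[keep],
    )
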