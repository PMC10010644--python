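"""Synthetic chest-phantom images with rule-generated reports.

The phantom is a desk-scale stand-in for an X-ray/report pair: a fixed
parametric torso template (two lung ellipses and a heart ellipse) with
additive Gaussian noise, on which zero or more localized "pathologies"
are planted as smooth brightness modifications.  Each planted pathology
comes with a ground-truth binary mask, so attention-localization can be
scored exactly.  Reports are produced by a small template grammar — one
declarative findings sentence per pathology, drawn from a few surface
variants — and the pathology label tokens are prepended to the report
text, emulating labeller-prefixed training targets.

Everything is a pure function of ``(spec.seed, index)``: per-sample
generators are derived with ``numpy.random.SeedSequence`` so random
access is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .report_prep import assemble_report, normalize_text, prepend_labels


class ConfigurationError(ValueError):
    pass


PATHOLOGY_KINDS = ("opacity_left", "opacity_right", "enlarged_heart", "device_line", "none")

# surface variants per pathology; the variant is picked from the sample RNG
_FINDINGS = {
    "opacity_left": (
        "there is a focal opacity in the left lung",
        "a patchy opacity is seen in the left lung",
        "the left lung shows an area of increased opacity",
    ),
    "opacity_right": (
        "there is a focal opacity in the right lung",
        "a patchy opacity is seen in the right lung",
        "the right lung shows an area of increased opacity",
    ),
    "enlarged_heart": (
        "the cardiac silhouette is enlarged",
        "the heart and cardiac silhouette appear enlarged",
        "there is enlargement of the cardiac silhouette",
    ),
    "device_line": (
        "a support line projects over the chest",
        "a thin support line is seen over the chest",
        "a monitoring line overlies the chest",
    ),
}

_IMPRESSION = {
    "opacity_left": "left lung opacity",
    "opacity_right": "right lung opacity",
    "enlarged_heart": "cardiomegaly",
    "device_line": "support device in place",
    "none": "no acute findings",
}

_NORMAL_SENTENCE = "the lungs are clear and the cardiac silhouette is normal"


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom corpus."""

    image_size: int = 224
    catalogue: tuple = PATHOLOGY_KINDS
    max_pathologies_per_image: int = 2
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ConfigurationError("image_size must be positive")
        if not self.catalogue:
            raise ConfigurationError("pathology catalogue must be non-empty")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        unknown = set(self.catalogue) - set(PATHOLOGY_KINDS)
        if unknown:
            raise ConfigurationError(f"unknown pathology kinds: {sorted(unknown)}")


@dataclass
class PhantomSample:
    image: np.ndarray                 # (size, size) float, values in [0, 1]
    report: str                       # label tokens prepended
    impression: str
    findings: str
    labels: tuple                     # pathology kinds, sorted
    masks: dict = field(default_factory=dict)  # kind -> bool (size, size)
    sample_id: str = ""


def label_token(kind: str) -> str:
    """The single normalized token that marks ``kind`` in report text."""
    return normalize_text(kind)[0]


def _base_geometry(size: int, heart_scale: float = 1.0):
    """Noise-free template plus the region masks used for lesions."""
    y, x = np.mgrid[0:size, 0:size] / (size - 1)
    img = np.full((size, size), 0.05)
    torso = ((x - 0.5) / 0.42) ** 2 + ((y - 0.52) / 0.46) ** 2 <= 1.0
    img[torso] = 0.35
    lung_l = ((x - 0.32) / 0.16) ** 2 + ((y - 0.45) / 0.28) ** 2 <= 1.0
    lung_r = ((x - 0.68) / 0.16) ** 2 + ((y - 0.45) / 0.28) ** 2 <= 1.0
    img[lung_l] = 0.15
    img[lung_r] = 0.15
    heart = (((x - 0.56) / (0.11 * heart_scale)) ** 2
             + ((y - 0.60) / (0.15 * heart_scale)) ** 2) <= 1.0
    img[heart] = 0.48
    return img, {"lung_l": lung_l, "lung_r": lung_r, "heart": heart,
                 "torso": torso, "x": x, "y": y}


def _render(size: int, labels: tuple, rng: np.random.Generator):
    """Noise-free image plus per-pathology masks for the given label set."""
    heart_scale = 1.45 if "enlarged_heart" in labels else 1.0
    img, geo = _base_geometry(size, heart_scale=heart_scale)
    masks = {}
    if "enlarged_heart" in labels:
        normal, ngeo = _base_geometry(size, heart_scale=1.0)
        masks["enlarged_heart"] = geo["heart"] & ~ngeo["heart"]
    x, y = geo["x"], geo["y"]
    for kind, lung_key, cx0 in (("opacity_left", "lung_l", 0.32),
                                ("opacity_right", "lung_r", 0.68)):
        if kind in labels:
            cx = cx0 + rng.uniform(-0.07, 0.07)
            cy = 0.45 + rng.uniform(-0.14, 0.14)
            sigma = rng.uniform(0.035, 0.055)
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            blob = 0.40 * np.exp(-r2 / (2 * sigma ** 2))
            img = img + blob
            masks[kind] = (blob >= 0.20) & geo[lung_key]
    if "device_line" in labels:
        x0 = rng.uniform(0.30, 0.70)
        slope = rng.uniform(-0.25, 0.25)
        dist = np.abs((x - x0) - slope * (y - 0.1))
        line = (dist <= 0.008) & geo["torso"] & (y < 0.75)
        img = np.where(line, np.minimum(img + 0.35, 1.0), img)
        masks["device_line"] = line
    return np.clip(img, 0.0, 1.0), masks


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_phantom(spec: PhantomSpec, index: int) -> PhantomSample:
    """Render phantom ``index`` of the corpus defined by ``spec``."""
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = _sample_rng(spec.seed, index)
    kinds = [k for k in spec.catalogue if k != "none"]
    if kinds and rng.random() >= 0.25:
        n = int(rng.integers(1, min(spec.max_pathologies_per_image, len(kinds)) + 1))
        labels = tuple(sorted(rng.choice(kinds, size=n, replace=False).tolist()))
    else:
        labels = ("none",)

    img, masks = _render(spec.image_size, labels, rng)
    if spec.noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sigma, img.shape), 0.0, 1.0)

    if labels == ("none",):
        findings = _NORMAL_SENTENCE + " ."
    else:
        sentences = []
        for kind in labels:
            variants = _FINDINGS[kind]
            sentences.append(variants[int(rng.integers(len(variants)))] + " .")
        findings = " ".join(sentences)
    impression = " and ".join(_IMPRESSION[k] for k in labels) + " ."
    body = assemble_report(impression, findings)
    report = prepend_labels([label_token(k) for k in labels], body)
    return PhantomSample(image=img.astype(np.float32), report=report,
                         impression=impression, findings=findings,
                         labels=labels, masks=masks,
                         sample_id=f"phantom-{index:06d}")


def generate_dataset(spec: PhantomSpec, n: int, out_image_store, out_reports,
                     out_manifest=None) -> list:
    """Write ``n`` phantoms to HDF5 (images) and JSON-lines (reports).

    Images are stored under the dataset name ``images`` with shape
    (n, 1, size, size), dtype float32, values in [0, 1].  Returns the
    manifest: the ordered list of sample ids.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    out_image_store = Path(out_image_store)
    out_reports = Path(out_reports)
    manifest = []
    try:
        with h5py.File(out_image_store, "w") as h5, open(out_reports, "w") as rep:
            dset = h5.create_dataset(
                "images", shape=(n, 1, spec.image_size, spec.image_size),
                dtype="float32")
            for i in range(n):
                s = generate_phantom(spec, i)
                dset[i, 0] = s.image
                rec = {"sample_id": s.sample_id, "impression": s.impression,
                       "findings": s.findings, "labels": list(s.labels)}
                rep.write(json.dumps(rec, sort_keys=True, separators=(",", ":")) + "\n")
                manifest.append(s.sample_id)
    except OSError as exc:
        raise OSError(f"failed writing phantom dataset near "
                      f"{out_image_store} / {out_reports}: {exc}") from exc
    if out_manifest is not None:
        Path(out_manifest).write_text("\n".join(manifest) + "\n")
    return manifest


DEFAULT_FRACTIONS = (0.75, 0.2475, 0.0025)


def split_dataset(manifest, fractions=DEFAULT_FRACTIONS, seed: int = 0):
    """Deterministic disjoint train/val/test partition of the manifest ids."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    ids = list(manifest)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * fractions[0]))
    n_val = int(np.floor(len(ids) * fractions[1]))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:n_train + n_val]]
    test = [ids[i] for i in order[n_train + n_val:]]
    return train, val, test


def load_images(image_store) -> np.ndarray:
    with h5py.File(image_store, "r") as h5:
        return h5["images"][...]


def load_reports(path) -> list:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records
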