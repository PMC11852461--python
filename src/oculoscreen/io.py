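"""Readers, writers, run configuration and the umbrella pipeline.

All tabular artifacts are CSV with a first-line schema comment
(``# oculoscreen-schema <name> v1``) so downstream tooling can verify what
it is reading; every pipeline run writes its fully-resolved configuration
and a checksum manifest next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidInputError
from .features import FEATURE_NAMES, SubjectSeries
from .geometry import EyeFrame

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    out_dir: str = "runs/out"
    seed: int = 0
    n_normal: int = 35
    n_patient: int = 35
    model: str = "rf"
    write_images: bool = False
    stages: tuple[str, ...] = ("simulate", "featurize", "classify", "explain")
    # extraction parameters
    blur_kernel: int = 5
    min_area: int = 100
    cos_threshold: float = 0.3
    delta_hi: float = 3.0
    delta_lo: float = 1.5
    neighbor_stride: int = 4
    mode_bin_width: float = 0.01
    smoothing_window: int = 15
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.model not in ("rf", "lr", "dt", "svm", "knn", "nb", "gbdt", "ab"):
            raise ConfigError(f"unknown model {cfg.model!r}")
        return cfg

    def to_json(self, path: Path | str) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(json.dumps(d, indent=2))


# ---------------------------------------------------------------------------
# frames

_FRAME_RE = re.compile(r"sub(?P<sub>[^_]+)_(?P<side>[LR])_(?P<idx>\d{4})\.png$")


def write_frames(frames: Sequence[EyeFrame], out_dir: Path | str, subject_id: str) -> list[Path]:
    """Write a PNG stack ``sub{ID}_{L|R}_{frame:04d}.png``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        tag = "L" if fr.side == "left" else "R"
        p = out / f"sub{subject_id}_{tag}_{fr.index:04d}.png"
        iio.imwrite(p, fr.image)
        paths.append(p)
    return paths


def read_frames(path: Path | str, layout: str = "auto") -> tuple[dict, dict]:
    """Read per-eye frame sequences.

    Returns ``(streams, gap_report)``: ``streams`` maps
    ``(subject_id, side)`` to an index-ordered list of :class:`EyeFrame`;
    ``gap_report`` maps the same key to the sorted list of missing frame
    indices (holes in the numbering), reported rather than raised.

    ``layout`` is ``"png-stack"`` (a directory of ``sub*_L_0000.png``
    files), ``"video"`` (any imageio-readable container; all frames one
    stream), or ``"auto"`` (directory -> png-stack, file -> video).
    """
    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"no such path: {p}")
    if layout == "auto":
        layout = "png-stack" if p.is_dir() else "video"
    if layout == "video":
        frames = [
            EyeFrame(np.asarray(img) if np.asarray(img).ndim == 2 else np.asarray(img)[..., 0], index=i)
            for i, img in enumerate(iio.imiter(p))
        ]
        if not frames:
            raise InvalidInputError(f"no frames decodable from {p}")
        return {("video", "left"): frames}, {}
    entries: dict[tuple[str, str], dict[int, EyeFrame]] = {}
    for f in sorted(p.iterdir()):
        m = _FRAME_RE.match(f.name)
        if not m:
            continue
        side = "left" if m["side"] == "L" else "right"
        idx = int(m["idx"])
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[..., 0]
        entries.setdefault((m["sub"], side), {})[idx] = EyeFrame(img, side=side, index=idx)
    if not entries:
        raise InvalidInputError(f"no frame files matching sub*_L|R_*.png in {p}")
    streams, gaps = {}, {}
    for key, d in entries.items():
        idxs = sorted(d)
        missing = sorted(set(range(idxs[0], idxs[-1] + 1)) - set(idxs))
        if missing:
            gaps[key] = missing
        streams[key] = [d[i] for i in idxs]
    return streams, gaps


# ---------------------------------------------------------------------------
# CSV schemas

def _write_csv(df: pd.DataFrame, path: Path | str, schema: str) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write(f"# oculoscreen-schema {schema} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path | str, schema: str) -> pd.DataFrame:
    p = Path(path)
    with open(p) as fh:
        header = fh.readline()
        if schema not in header:
            raise InvalidInputError(f"{p} is not an oculoscreen {schema} CSV")
        return pd.read_csv(fh)


def write_series_csv(series: SubjectSeries, path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "E_left": series.E_left,
            "E_right": series.E_right,
            "E_avg": series.E_avg,
        }
    )
    _write_csv(df, path, "series")


def read_series_csv(
    path: Path | str,
    canthus_dists: tuple[float, float] = (60.0, 180.0),
    subject_id: str = "",
    label: str | None = None,
) -> SubjectSeries:
    df = _read_csv(path, "series")
    return SubjectSeries(
        E_left=df["E_left"].to_numpy(),
        E_right=df["E_right"].to_numpy(),
        canthus_dists=canthus_dists,
        subject_id=subject_id,
        label=label,
    )


def write_pupil_csv(results, path: Path | str) -> None:
    """Per-frame pupil geometry (frame, x_o, y_o, a, b, tilt, flags)."""
    rows = []
    for i, r in enumerate(results):
        e = r.ellipse
        rows.append(
            {
                "frame": i,
                "x_o": e.center[0] if e else np.nan,
                "y_o": e.center[1] if e else np.nan,
                "a": e.a if e else np.nan,
                "b": e.b if e else np.nan,
                "tilt": e.tilt if e else np.nan,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    _write_csv(pd.DataFrame(rows), path, "pupil")


def write_canthus_csv(pairs, path: Path | str) -> None:
    rows = []
    for i, c in enumerate(pairs):
        rows.append(
            {
                "frame": i,
                "x_ci": c.inner[0],
                "y_ci": c.inner[1],
                "x_co": c.outer[0],
                "y_co": c.outer[1],
                "conf_ci": c.confidence_inner,
                "conf_co": c.confidence_outer,
            }
        )
    _write_csv(pd.DataFrame(rows), path, "canthus")


def write_feature_csv(features: pd.DataFrame, path: Path | str) -> None:
    _write_csv(features.reset_index(), path, "features")


def read_feature_csv(path: Path | str) -> pd.DataFrame:
    df = _read_csv(path, "features")
    return df.set_index("subject_id")


def write_manifest_csv(labels, profiles, path: Path | str) -> None:
    rows = []
    for i, (lab, prof) in enumerate(zip(labels, profiles)):
        row = {"subject_id": f"{'N' if lab == 'normal' else 'P'}{i:03d}", "label": lab}
        row.update(asdict(prof))
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path, "manifest")


# ---------------------------------------------------------------------------
# pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages end to end; returns the artifact directory.

    Stage outputs already present with matching checksums are reused; a
    checksum mismatch raises a :class:`ConfigError` naming the stage.
    Deterministic under a fixed seed.
    """
    from .classify import loocv_evaluate, model_comparison, shap_weights
    from .features import GazeFeaturizer
    from .simulator import generate_cohort, render_eye_frame, sample_scene

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest_path = out / "checksums.json"
    checksums = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    log: list[str] = []

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            checksums[str(p.relative_to(out))] = {"stage": stage, "sha256": _sha256(p)}
        manifest_path.write_text(json.dumps(checksums, indent=2))

    def verify(stage: str, *paths: Path) -> bool:
        """True if all paths exist and match recorded checksums."""
        for p in paths:
            rel = str(p.relative_to(out))
            if not p.exists() or rel not in checksums:
                return False
            if checksums[rel]["sha256"] != _sha256(p):
                raise ConfigError(f"checksum mismatch for {rel} (stage {stage})")
        return True

    series = labels = profiles = None

    def ensure_cohort():
        nonlocal series, labels, profiles
        if series is None:
            series, labels, profiles = generate_cohort(
                config.n_normal, config.n_patient, seed=config.seed
            )
        return series, labels, profiles

    try:
        if "simulate" in config.stages:
            series_dir = out / "series"
            manifest = out / "cohort_manifest.csv"
            s, lab, prof = ensure_cohort()
            paths = []
            for subj in s:
                sp = series_dir / f"{subj.subject_id}.csv"
                write_series_csv(subj, sp)
                paths.append(sp)
            write_manifest_csv(lab, prof, manifest)
            record("simulate", manifest, *paths)
            if config.write_images:
                rng = np.random.default_rng(config.seed)
                scene = sample_scene(rng)
                fr = [render_eye_frame(scene, seed=config.seed + i, index=i) for i in range(3)]
                write_frames(fr, out / "frames", s[0].subject_id)
            log.append(f"simulate: {len(s)} subjects")

        if "featurize" in config.stages:
            fpath = out / "features.csv"
            if not verify("featurize", fpath):
                s, lab, prof = ensure_cohort()
                feat = GazeFeaturizer().fit(s, lab)
                X = feat.transform(s)
                df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
                df.insert(0, "label", lab)
                df.index = pd.Index([x.subject_id for x in s], name="subject_id")
                write_feature_csv(df, fpath)
                record("featurize", fpath)
            log.append("featurize: features.csv")

        if "classify" in config.stages:
            s, lab, prof = ensure_cohort()
            rep = loocv_evaluate(s, config.model, seed=config.seed)
            report = {
                "model": config.model,
                "seed": config.seed,
                "confusion": {"tp": rep.tp, "fn": rep.fn, "fp": rep.fp, "tn": rep.tn},
                "metrics": rep.metrics(),
            }
            (out / "report.json").write_text(json.dumps(report, indent=2))
            table = model_comparison(s, seed=config.seed).reset_index()
            _write_csv(table, out / "model_comparison.csv", "model-comparison")
            record("classify", out / "report.json", out / "model_comparison.csv")
            log.append(f"classify: accuracy={rep.accuracy:.3f}")

        if "explain" in config.stages:
            s, lab, prof = ensure_cohort()
            att = shap_weights(s, config.model, seed=config.seed)
            wdf = att.weights.rename("weight").rename_axis("feature").reset_index()
            _write_csv(wdf, out / "attribution.csv", "attribution")
            record("explain", out / "attribution.csv")
            log.append("explain: attribution.csv")
    except Exception as exc:
        (out / "error.log").write_text(f"pipeline aborted: {exc}\n" + "\n".join(log))
        raise

    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
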