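"""Study configuration and the five-step pipeline driver.

Steps run in the fixed order clean -> calibrate -> reconstruct -> normalize
-> stats; per-subject intermediates are persisted in standard formats and a
JSON manifest records a state hash per step so re-running a completed step
with unchanged inputs and parameters is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .calibrate import calibrate_subject
from .core import Volume
from .errors import ConfigError, DependencyError
from .preprocess import CleaningParams, clean_subject
from .reconstruct import align_stack_center_out, stack_sections
from .normalize import normalize_subject, smooth_template
from .stats import GroupData, analyze_group

STEP_ORDER = ["clean", "calibrate", "reconstruct", "normalize", "stats"]

_DEFAULTS = {
    "version": 1,
    "seed": 0,
    "output_dir": "out",
    "spacing": [10.0, 10.0],
    "section_thickness": 20.0,
    "template_subject": None,
    "subjects": [],
    "cleaning": {
        "opening_radius": 50.0,
        "min_component_pixels": 1,
        "tissue_bright": True,
    },
    "calibration": {"method": "spline", "out_of_range": "clamp"},
    "reconstruction": {
        "downsample": 4,
        "refine_full": True,
        "search_shift": 250.0,
        "search_angle": 8.0,
    },
    "normalization": {"fwhm_factor": 3.0, "grid_spacing": None},
    "statistics": {
        "fwhm_factor": 3.0,
        "q_fdr": 0.05,
        "alpha_fwe": 0.05,
        "fwe_method": "bonferroni",
        "min_cluster_size": 1,
        "alpha_cluster": None,
    },
}

_SUBJECT_KEYS = {"id", "sections", "standards", "group"}


@dataclass
class StudyConfig:
    """Validated study configuration (see ``_DEFAULTS`` for the schema)."""

    data: dict
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir=Path(".")) -> "StudyConfig":
        data = _merge_with_defaults(raw)
        cfg = cls(data, Path(base_dir))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        subjects = self.data["subjects"]
        if not subjects:
            raise ConfigError("config lists no subjects")
        ids = [s["id"] for s in subjects]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate subject ids")
        for s in subjects:
            extra = set(s) - _SUBJECT_KEYS
            if extra:
                raise ConfigError(f"unknown subject keys {sorted(extra)}")
            if s.get("group") not in {"A", "B"}:
                raise ConfigError(f"subject {s['id']}: group must be 'A' or 'B'")
            for key in ("sections", "standards"):
                p = self.resolve(s[key])
                if not p.exists():
                    raise ConfigError(f"subject {s['id']}: missing path {p}")
        tmpl = self.data["template_subject"]
        if tmpl not in ids and not self.resolve(str(tmpl)).exists():
            raise ConfigError(
                f"template_subject {tmpl!r} is neither a subject id nor a path"
            )

    def resolve(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def out_dir(self) -> Path:
        return self.resolve(self.data["output_dir"])

    @property
    def subjects(self) -> list[dict]:
        return self.data["subjects"]

    def __getitem__(self, key):
        return self.data[key]


def _merge_with_defaults(raw: dict) -> dict:
    def merge(defaults, values, path=""):
        if not isinstance(values, dict):
            raise ConfigError(f"expected a mapping at {path or 'top level'}")
        out = {}
        unknown = set(values) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown config keys at {path or 'top level'}: "
                              f"{sorted(unknown)}")
        for key, default in defaults.items():
            if key in values:
                if isinstance(default, dict) and key != "subjects":
                    out[key] = merge(default, values[key], f"{path}{key}.")
                else:
                    out[key] = values[key]
            else:
                out[key] = json.loads(json.dumps(default))
        return out

    return merge(_DEFAULTS, raw)


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_files(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(map(str, paths)):
        h.update(p.encode())
        h.update(hashlib.sha256(Path(p).read_bytes()).digest())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Per-step completion state persisted as JSON in the output directory."""

    path: Path
    steps: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunManifest":
        path = Path(path)
        steps = {}
        if path.exists():
            steps = json.loads(path.read_text()).get("steps", {})
        return cls(path, steps)

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps({"steps": self.steps}, indent=2))

    def is_current(self, step: str, state_hash: str) -> bool:
        entry = self.steps.get(step)
        if not entry or entry.get("state_hash") != state_hash:
            return False
        return all(Path(p).exists() for p in entry.get("outputs", []))

    def record(self, step: str, state_hash: str, outputs) -> None:
        self.steps[step] = {
            "state_hash": state_hash,
            "outputs": [str(p) for p in outputs],
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "status": "completed",
        }
        self.save()


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


class Pipeline:
    """Executes the five processing steps for one study configuration."""

    def __init__(self, config: StudyConfig):
        self.cfg = config
        self.out = config.out_dir
        self.work = self.out / "work"
        self.manifest = RunManifest.load(self.out / "manifest.json")

    # ---- per-step state hashes (chained so downstream reruns when
    # anything upstream changed)
    def _state_hash(self, step: str) -> str:
        cfg = self.cfg.data
        chain = {"step": step, "seed": cfg["seed"]}
        if step == "clean":
            files = []
            for s in self.cfg.subjects:
                files += sorted(self.cfg.resolve(s["sections"]).glob("*_s*.tif"))
            chain["inputs"] = _hash_files(files)
            chain["params"] = cfg["cleaning"]
        elif step == "calibrate":
            chain["upstream"] = self._state_hash("clean")
            chain["params"] = cfg["calibration"]
            chain["standards"] = _hash_files(
                [self.cfg.resolve(s["standards"]) for s in self.cfg.subjects]
            )
        elif step == "reconstruct":
            chain["upstream"] = self._state_hash("calibrate")
            chain["params"] = {**cfg["reconstruction"], "dz": cfg["section_thickness"]}
        elif step == "normalize":
            chain["upstream"] = self._state_hash("reconstruct")
            chain["params"] = {**cfg["normalization"],
                               "template": cfg["template_subject"]}
        elif step == "stats":
            chain["upstream"] = self._state_hash("normalize")
            chain["params"] = cfg["statistics"]
        return _hash_obj(chain)

    def _require(self, step: str) -> None:
        if not self.manifest.is_current(step, self._state_hash(step)):
            raise DependencyError(
                f"step '{step}' has not been run (or is stale); run it first"
            )

    def run(self, steps=None) -> RunManifest:
        steps = set(steps or STEP_ORDER)
        unknown = steps - set(STEP_ORDER)
        if unknown:
            raise ConfigError(f"unknown steps {sorted(unknown)}")
        for step in STEP_ORDER:
            if step not in steps:
                continue
            state = self._state_hash(step)
            if self.manifest.is_current(step, state):
                continue
            idx = STEP_ORDER.index(step)
            if idx > 0:
                self._require(STEP_ORDER[idx - 1])
            outputs = getattr(self, f"_step_{step}")()
            self.manifest.record(step, state, outputs)
        return self.manifest

    # ---- steps
    def _step_clean(self):
        params = CleaningParams(**self.cfg["cleaning"])
        outputs = []
        for s in self.cfg.subjects:
            raw = aio.read_sections(
                self.cfg.resolve(s["sections"]),
                spacing=tuple(self.cfg["spacing"]),
                subject=s["id"],
            )
            cleaned = clean_subject(raw, params)
            outputs += aio.write_sections(
                cleaned, self.work / s["id"] / "cleaned", s["id"], write_masks=True
            )
        return outputs

    def _step_calibrate(self):
        params = self.cfg["calibration"]
        outputs = []
        for s in self.cfg.subjects:
            cleaned = aio.read_sections(
                self.work / s["id"] / "cleaned",
                spacing=tuple(self.cfg["spacing"]),
                subject=s["id"],
                with_masks=True,
            )
            standards = aio.read_standards(self.cfg.resolve(s["standards"]))
            calibrated, _ = calibrate_subject(
                cleaned, standards, method=params["method"],
                out_of_range=params["out_of_range"],
            )
            for sec in calibrated:
                sec.pixels = sec.pixels.astype(np.float32)
            outputs += aio.write_sections(
                calibrated, self.work / s["id"] / "calibrated", s["id"],
                write_masks=True,
            )
        return outputs

    def _step_reconstruct(self):
        params = self.cfg["reconstruction"]
        outputs = []
        for s in self.cfg.subjects:
            secs = aio.read_sections(
                self.work / s["id"] / "calibrated",
                spacing=tuple(self.cfg["spacing"]),
                subject=s["id"],
                require_uint8=False,
                with_masks=True,
            )
            stack = stack_sections(secs, self.cfg["section_thickness"])
            aligned, report, _ = align_stack_center_out(
                stack,
                downsample=params["downsample"],
                refine_full=params["refine_full"],
                search_shift=params["search_shift"],
                search_angle=params["search_angle"],
            )
            path = aio.write_volume(aligned, self.work / s["id"] / "recon.nii.gz")
            rpt = {
                "ncc_before": report.per_pair_ncc_before,
                "ncc_after": report.per_pair_ncc_after,
                "converged": report.converged_flags,
            }
            rpath = self.work / s["id"] / "recon_report.json"
            rpath.write_text(json.dumps(rpt, indent=2))
            outputs += [path, rpath]
        return outputs

    def _step_normalize(self):
        params = self.cfg["normalization"]
        tmpl_id = self.cfg["template_subject"]
        ids = [s["id"] for s in self.cfg.subjects]
        if tmpl_id in ids:
            template = aio.read_volume(self.work / tmpl_id / "recon.nii.gz")
        else:
            template = aio.read_volume(self.cfg.resolve(str(tmpl_id)))
        outputs = []
        for s in self.cfg.subjects:
            vol = aio.read_volume(self.work / s["id"] / "recon.nii.gz")
            warped, _, _ = normalize_subject(
                vol, template, fwhm_factor=params["fwhm_factor"],
                grid_spacing=params["grid_spacing"],
            )
            outputs.append(
                aio.write_volume(warped, self.work / s["id"] / "norm.nii.gz")
            )
        tmask = smooth_template(template, params["fwhm_factor"]).mask
        if tmask is not None:
            outputs.append(aio.write_volume(
                Volume(tmask.astype(np.uint8), template.spacing,
                       origin=template.origin),
                self.work / "template_mask.nii.gz",
            ))
        return outputs

    def _step_stats(self):
        params = self.cfg["statistics"]
        volumes, labels = [], []
        for s in self.cfg.subjects:
            volumes.append(aio.read_volume(self.work / s["id"] / "norm.nii.gz"))
            labels.append(s["group"])
        mask = None
        tmask_path = self.work / "template_mask.nii.gz"
        if tmask_path.exists():
            mask = aio.read_volume(tmask_path, with_mask=False).voxels > 0
            for v in volumes:
                if v.mask is not None:
                    mask &= v.mask
        data = GroupData(volumes, labels, analysis_mask=mask)
        maps = analyze_group(
            data,
            fwhm_factor=params["fwhm_factor"],
            q_fdr=params["q_fdr"],
            alpha_fwe=params["alpha_fwe"],
            fwe_method=params["fwe_method"],
            min_cluster_size=params["min_cluster_size"],
            alpha_cluster=params["alpha_cluster"],
            seed=self.cfg["seed"],
        )
        stats_dir = self.out / "stats"
        stats_dir.mkdir(parents=True, exist_ok=True)
        ref = volumes[0]

        def vol(arr):
            return Volume(arr, ref.spacing, origin=ref.origin)

        outputs = [
            aio.write_volume(vol(maps.t_map), stats_dir / "tmap.nii.gz"),
            aio.write_volume(vol(maps.p_pos), stats_dir / "p_pos.nii.gz"),
            aio.write_volume(vol(maps.p_neg), stats_dir / "p_neg.nii.gz"),
            aio.write_volume(vol(maps.p_fwe), stats_dir / "p_fwe.nii.gz"),
            aio.write_volume(vol(maps.q_fdr), stats_dir / "q_fdr.nii.gz"),
            aio.write_volume(
                vol(maps.cluster_labels.astype(np.int32)),
                stats_dir / "clusters.nii.gz",
            ),
        ]
        maps.cluster_table.to_csv(stats_dir / "clusters.csv", index=False)
        outputs.append(stats_dir / "clusters.csv")
        aio.write_montage(ref, stats_dir / "montage.png",
                          overlay=maps.cluster_labels)
        outputs.append(stats_dir / "montage.png")
        return outputs


def run_pipeline(config: StudyConfig, steps=None) -> RunManifest:
    """Run the requested steps (default: all five) for a study."""
    return Pipeline(config).run(steps)
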