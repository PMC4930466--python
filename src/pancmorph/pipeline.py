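"""End-to-end orchestration: manifest-driven runs, provenance, blinding.

A run executes volume -> FD -> fat -> report for every participant-timepoint
listed in a JSON manifest, isolating per-participant failures and writing one
CSV per stage plus a provenance record. Outputs are byte-identical across
reruns with the same config and inputs: all randomness flows from one root
seed split deterministically per stage, and provenance records digests and
configuration rather than wall-clock timestamps (a timestamp would break the
rerun-identity contract; pass ``timestamps=True`` to include one anyway).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dixon import CircularROI, DixonTriplet, dixon_separate, mean_ff_in_rois, pancreas_fat_percent
from .errors import InputError, ParameterError
from .fractal import fd_of_mask
from .mask import load_mask
from .stats import summarize_group
from .volumetry import compute_volume, pancreas_volume_index

__all__ = ["RunConfig", "ProvenanceLog", "run_pipeline", "blind_labels", "unblind_labels"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serialisable run configuration; CLI flags override file values."""

    seed: int = 0
    projection_axis: str = "anterior_posterior"
    n_offsets: int = 10
    n_replicates: int = 2
    output_dir: str = "pancmorph_out"
    log_level: str = "INFO"
    timestamps: bool = False

    def __post_init__(self) -> None:
        if self.n_offsets < 1 or self.n_replicates < 1:
            raise ParameterError("n_offsets and n_replicates must be >= 1")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ProvenanceLog:
    """One entry per output file: inputs digests, config, version, seed."""

    entries: dict = field(default_factory=dict)

    def record(self, output: str, inputs: list[str], config: RunConfig) -> None:
        digests = {}
        for p in inputs:
            h = hashlib.sha256()
            h.update(Path(p).read_bytes())
            digests[Path(p).name] = h.hexdigest()
        # output_dir is a deployment detail, not part of the analysis identity
        cfg = {k: v for k, v in asdict(config).items() if k != "output_dir"}
        entry = {
            "input_digests": digests,
            "config": cfg,
            "package_version": __version__,
            "seed": config.seed,
        }
        if config.timestamps:
            entry["timestamp"] = datetime.now(timezone.utc).isoformat()
        self.entries[Path(output).name] = entry

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage_seed(root_seed: int, stage: str, participant: str, timepoint: str) -> int:
    """Deterministic per-(stage, participant, timepoint) substream below 2**31."""
    h = hashlib.sha256(f"{root_seed}:{stage}:{participant}:{timepoint}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _load_rois_for_fat(entry: dict) -> list[CircularROI]:
    return [CircularROI(tuple(r["center"]), r.get("area_mm2", 100.0)) for r in entry]


def run_pipeline(config: RunConfig, manifest_path: str) -> dict:
    """Execute the full pipeline over a manifest.

    Manifest schema (JSON)::

        {"participants": [
            {"id": "R01", "timepoint": "baseline", "mask": "R01_baseline.nii.gz",
             "bmi": 34.0,
             "dixon": {"slices": [
                 {"in_phase": "...", "opposed_phase": "...", "third_echo": "...",
                  "rois": [{"center": [r, c], "area_mm2": 100}, ...]},
                 {...}]}},
            ...],
         "cohort_csv": "cohort.csv"}

    Relative paths resolve against the manifest directory. Per-participant
    failures are logged and summarised; the run fails only if every
    participant fails.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = ProvenanceLog()

    vol_rows, fd_rows, fat_rows, failures = [], [], [], []
    for entry in manifest.get("participants", []):
        pid = entry["id"]
        tp = entry.get("timepoint", "baseline")
        try:
            inputs = []
            mask_path = base / entry["mask"]
            inputs.append(str(mask_path))
            mask = load_mask(str(mask_path))
            vol = compute_volume(mask)
            row = {
                "id": pid,
                "timepoint": tp,
                "volume_cm3": round(vol.volume_cm3, 6),
                "n_slices": vol.n_slices_with_roi,
            }
            if entry.get("bmi"):
                row["volume_index_cm3_m2_kg"] = round(
                    pancreas_volume_index(vol.volume_cm3, entry["bmi"]), 6
                )
            vol_rows.append(row)

            fd_seed = _stage_seed(config.seed, "fd", pid, tp)
            fd_res, precision = fd_of_mask(
                mask,
                axis=config.projection_axis,
                n_offsets=config.n_offsets,
                n_replicates=config.n_replicates,
                seed=fd_seed,
            )
            fd_rows.append(
                {
                    "id": pid,
                    "timepoint": tp,
                    "axis": config.projection_axis,
                    "fd": round(fd_res.fd, 6),
                    "cv_percent": round(precision.cv_percent, 6) if precision else "",
                    "n_sizes": fd_res.n_sizes,
                    "n_offsets": config.n_offsets,
                    "n_replicates": config.n_replicates,
                    "seed": fd_seed,
                }
            )

            if entry.get("dixon"):
                slice_means = []
                for sl in entry["dixon"]["slices"]:
                    echoes = []
                    for key in ("in_phase", "opposed_phase", "third_echo"):
                        p = base / sl[key]
                        inputs.append(str(p))
                        echoes.append(_load_echo(str(p)))
                    ff = dixon_separate(DixonTriplet(*echoes))
                    rois = _load_rois_for_fat(sl["rois"])
                    slice_means.append(mean_ff_in_rois(ff, rois))
                fat_rows.append(
                    {
                        "id": pid,
                        "timepoint": tp,
                        "slice1_ff_pct": round(slice_means[0], 6),
                        "slice2_ff_pct": round(slice_means[1], 6),
                        "pancreas_fat_pct": round(pancreas_fat_percent(slice_means), 6),
                    }
                )
        except Exception as exc:  # isolation contract: one bad participant must not sink the run
            logger.error("participant %s/%s failed: %s", pid, tp, exc)
            failures.append({"id": pid, "timepoint": tp, "error": str(exc)})
            continue

    outputs = {}
    for name, rows in [("volume", vol_rows), ("fd", fd_rows), ("fat", fat_rows)]:
        if rows:
            path = outdir / f"{name}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            prov.record(path, [str(manifest_path)], config)
            outputs[name] = str(path)

    if manifest.get("cohort_csv"):
        cohort_path = base / manifest["cohort_csv"]
        cohort = pd.read_csv(cohort_path)
        merged = cohort
        if vol_rows:
            merged = merged.merge(
                pd.DataFrame(vol_rows)[["id", "timepoint", "volume_cm3"]],
                on=["id", "timepoint"],
                how="left",
            )
        summary = summarize_group(merged)
        table_path = outdir / "report_cells.csv"
        contrasts_path = outdir / "report_contrasts.csv"
        summary.cells.to_csv(table_path, index=False, float_format="%.6g")
        summary.contrasts.to_csv(contrasts_path, index=False, float_format="%.6g")
        prov.record(table_path, [str(cohort_path)], config)
        prov.record(contrasts_path, [str(cohort_path)], config)
        outputs["report_cells"] = str(table_path)
        outputs["report_contrasts"] = str(contrasts_path)

    prov_path = outdir / "provenance.json"
    prov.write(prov_path)
    outputs["provenance"] = str(prov_path)

    n_total = len(manifest.get("participants", []))
    if failures and len(failures) == n_total and n_total > 0:
        raise InputError(f"all {n_total} participants failed; first: {failures[0]}")
    summary_path = outdir / "run_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(
            {"n_participants": n_total, "n_failed": len(failures), "failures": failures},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    outputs["run_summary"] = str(summary_path)
    return outputs


def _load_echo(path: str) -> np.ndarray:
    """Load one echo image: NIfTI real/imaginary pair convention (2-volume 3D
    file) or a plain 2D magnitude image."""
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 3 and data.shape[2] == 2:
        return data[:, :, 0] + 1j * data[:, :, 1]
    if data.ndim == 2:
        return data
    if data.ndim == 3 and data.shape[2] == 1:
        return data[:, :, 0]
    raise InputError(f"echo image {path} must be 2D or a 2-volume real/imag pair")


def save_echo(arr: np.ndarray, path: str, pixel_spacing=(1.0, 1.0)) -> None:
    """Write an echo image in the convention of :func:`_load_echo`."""
    import nibabel as nib

    arr = np.asarray(arr)
    if np.iscomplexobj(arr):
        data = np.stack([arr.real, arr.imag], axis=-1)
    else:
        data = arr[..., None]
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), path)


def blind_labels(cohort_csv: str, seed: int, out_csv: str, key_csv: str) -> None:
    """Replace participant ids with opaque codes and strip group labels.

    Mirrors the blinded-analysis discipline of morphometry studies: the
    blinded table carries no group or timepoint-identifying columns beyond
    the measurement rows themselves; the key file restores the mapping.
    """
    df = pd.read_csv(cohort_csv)
    if "timepoint" in df.columns and df.duplicated(["id", "timepoint"]).any():
        raise InputError("duplicate (id, timepoint) rows in cohort table")
    ids = df["id"].drop_duplicates().tolist()
    rng = np.random.default_rng(seed)
    codes = [f"P{c:04d}" for c in rng.permutation(9999)[: len(ids)] + 1]
    mapping = dict(zip(ids, codes))
    blinded = df.copy()
    blinded["id"] = blinded["id"].map(mapping)
    blinded = blinded.drop(columns=[c for c in ("group",) if c in blinded.columns])
    blinded = blinded.sort_values(["id", "timepoint"], kind="stable").reset_index(drop=True)
    blinded.to_csv(out_csv, index=False)
    pd.DataFrame({"code": list(mapping.values()), "id": list(mapping.keys())}).to_csv(
        key_csv, index=False
    )


def unblind_labels(blinded_csv: str, key_csv: str, cohort_csv: str, out_csv: str) -> None:
    """Invert :func:`blind_labels` using the key file and the original table's
    group column."""
    blinded = pd.read_csv(blinded_csv)
    key = pd.read_csv(key_csv)
    rev = dict(zip(key["code"], key["id"]))
    restored = blinded.copy()
    restored["id"] = restored["id"].map(rev)
    original = pd.read_csv(cohort_csv)
    if "group" in original.columns:
        groups = original[["id", "group"]].drop_duplicates()
        restored = restored.merge(groups, on="id", how="left")
        restored = restored[[c for c in original.columns if c in restored.columns]]
    # restore the original row order
    order = {k: i for i, k in enumerate(zip(original["id"], original["timepoint"]))}
    restored = (
        restored.assign(_ord=[order[k] for k in zip(restored["id"], restored["timepoint"])])
        .sort_values("_ord", kind="stable")
        .drop(columns="_ord")
        .reset_index(drop=True)
    )
    restored.to_csv(out_csv, index=False)
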