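"""Dataset manifest and file I/O.

A dataset is a YAML manifest naming per-subject matrix files (TSV or .npy,
time x channels), the sampling rate in Hz, channel labels and optional MNI
coordinates.  Fitted models go to an HDF5 container; tables (state time
courses, flips, statistics) are TSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import GroundTruth, SubjectRecording

__all__ = [
    "write_manifest",
    "read_manifest",
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_ground_truth",
    "read_ground_truth",
    "write_model",
    "read_model",
]


def write_recording(path: str | Path, recording: SubjectRecording) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, recording.data)
    else:
        pd.DataFrame(recording.data, columns=recording.channel_labels).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def read_recording(
    path: str | Path, fs: float, subject_id: str = "s0", channel_labels=None
) -> SubjectRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        df = pd.read_csv(path, sep="\t")
        if channel_labels is None:
            channel_labels = list(df.columns)
        data = df.to_numpy(float)
    return SubjectRecording(data, fs, subject_id=subject_id, channel_labels=channel_labels)


def write_manifest(
    path: str | Path,
    files: list[str],
    fs: float,
    channel_labels: list[str],
    subject_ids: list[str] | None = None,
    mni_coordinates: list[list[float]] | None = None,
) -> None:
    doc = {
        "fs": float(fs),
        "channel_labels": list(channel_labels),
        "recordings": [
            {"file": f, "subject_id": s}
            for f, s in zip(
                files, subject_ids or [f"s{i}" for i in range(len(files))]
            )
        ],
    }
    if mni_coordinates is not None:
        doc["mni_coordinates"] = [list(map(float, c)) for c in mni_coordinates]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    for key in ("fs", "channel_labels", "recordings"):
        if key not in doc:
            raise ValueError(f"manifest {path} is missing required key {key!r}")
    return doc


def write_dataset(
    out_dir: str | Path, recordings: list[SubjectRecording], fmt: str = "tsv"
) -> Path:
    """Write per-subject matrices plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for rec in recordings:
        name = f"{rec.subject_id}.{'npy' if fmt == 'npy' else 'tsv'}"
        write_recording(out_dir / name, rec)
        files.append(name)
    manifest = out_dir / "manifest.yaml"
    write_manifest(
        manifest,
        files,
        recordings[0].fs,
        recordings[0].channel_labels,
        [r.subject_id for r in recordings],
    )
    return manifest


def read_dataset(manifest_path: str | Path) -> list[SubjectRecording]:
    manifest_path = Path(manifest_path)
    doc = read_manifest(manifest_path)
    base = manifest_path.parent
    recs = []
    for entry in doc["recordings"]:
        f = base / entry["file"]
        rec = read_recording(
            f, doc["fs"], subject_id=entry["subject_id"],
            channel_labels=doc["channel_labels"],
        )
        if rec.n_channels != len(doc["channel_labels"]):
            raise ValueError(
                f"{f}: {rec.n_channels} channels but manifest lists "
                f"{len(doc['channel_labels'])} labels"
            )
        recs.append(rec)
    return recs


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("true_flips", data=truth.true_flips)
        g = h5.create_group("true_paths")
        for i, p in enumerate(truth.true_paths):
            g.create_dataset(str(i), data=p)
        h5.attrs["n_states"] = len(truth.specs)


def read_ground_truth(path: str | Path) -> tuple[list[np.ndarray], np.ndarray]:
    with h5py.File(path, "r") as h5:
        flips = h5["true_flips"][()]
        n = len(h5["true_paths"])
        paths = [h5["true_paths"][str(i)][()] for i in range(n)]
    return paths, flips


def write_model(path: str | Path, posterior, stc=None) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["K"] = posterior.K
        h5.create_dataset("transition_posterior", data=posterior.transition_posterior)
        h5.create_dataset("initial_posterior", data=posterior.initial_posterior)
        h5.create_dataset("state_scales", data=posterior.state_scales)
        h5.create_dataset("state_dofs", data=posterior.state_dofs)
        h5.create_dataset("prior_scale", data=posterior.prior_scale)
        h5.attrs["prior_dof"] = posterior.prior_dof
        h5.create_dataset("free_energy_trace", data=np.asarray(posterior.free_energy_trace))
        if stc is not None:
            g = h5.create_group("gamma")
            v = h5.create_group("viterbi")
            for i, (gam, path_i) in enumerate(zip(stc.gamma, stc.viterbi_path)):
                g.create_dataset(str(i), data=gam)
                v.create_dataset(str(i), data=path_i)


def read_model(path: str | Path):
    from .hmm import HMMPosterior, StateTimeCourses

    with h5py.File(path, "r") as h5:
        K = int(h5.attrs["K"])
        posterior = HMMPosterior(
            K=K,
            transition_posterior=h5["transition_posterior"][()],
            initial_posterior=h5["initial_posterior"][()],
            state_scales=h5["state_scales"][()],
            state_dofs=h5["state_dofs"][()],
            prior_transition=np.ones((K, K)),
            prior_initial=np.ones(K),
            prior_scale=h5["prior_scale"][()],
            prior_dof=float(h5.attrs["prior_dof"]),
            free_energy_trace=list(h5["free_energy_trace"][()]),
        )
        stc = None
        if "gamma" in h5:
            n = len(h5["gamma"])
            stc = StateTimeCourses(
                gamma=[h5["gamma"][str(i)][()] for i in range(n)],
                xi=[],
                viterbi_path=[h5["viterbi"][str(i)][()] for i in range(n)],
            )
    return posterior, stc
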