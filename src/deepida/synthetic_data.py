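"""Synthetic two-view generators with ground-truth signal masks.

The nonlinear generator produces two row-aligned views with two classes.
View 1 carries all the signal: its first ``0.1 p1`` columns follow the
spiral curves ``exp(0.15 theta) * sin(1.5 theta)`` (columns 1-5) and
``exp(0.15 theta) * cos(1.5 theta)`` (the rest), where ``theta`` is an
evenly spaced grid on ``[0, 3 pi]`` plus uniform jitter ``0.5 U(0,1)``.
The signal block is kept and everything else zeroed via an elementwise
ones/zeros mask, then i.i.d. ``0.2 N(0,1)`` noise is added everywhere.
View 2 is a noisy nonlinear distortion of view 1 with no signal columns
of its own: negatives clipped to zero, columns scaled to unit Euclidean
norm, plus ``U(0,1)`` noise per entry.

Classes are the two arms of the spiral: the first ``n1`` grid positions
(smaller theta) are class 1 and the remaining ``n2`` are class 2.  A
linear classifier on the raw columns separates these poorly, which is
the point of the design.

Four canonical settings cover the small/large sample and feature
regimes::

    S1: n1=200,  n2=150,  p1=p2=500
    S2: n1=3000, n2=2250, p1=p2=500
    S3: n1=200,  n2=150,  p1=p2=2000
    S4: n1=3000, n2=2250, p1=p2=2000
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MultiViewDataset",
    "SimSetting",
    "SETTINGS",
    "generate_nonlinear",
    "generate_linear_toy",
    "monte_carlo_replicates",
    "write_dataset",
    "read_dataset",
]


@dataclass
class MultiViewDataset:
    """Row-aligned view matrices, labels, and optional signal masks."""

    views: list[np.ndarray]
    labels: np.ndarray
    signal_masks: list[np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.views[0].shape[0]
        if any(X.shape[0] != n for X in self.views):
            raise ValueError("views do not share the same number of rows")
        if len(self.labels) != n:
            raise ValueError("labels length does not match views")
        if self.signal_masks is not None:
            for X, m in zip(self.views, self.signal_masks):
                if len(m) != X.shape[1]:
                    raise ValueError("signal mask length does not match view width")

    @property
    def n_samples(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.views)

    def subset_samples(self, idx) -> "MultiViewDataset":
        idx = np.asarray(idx)
        return MultiViewDataset(
            [X[idx] for X in self.views],
            np.asarray(self.labels)[idx],
            self.signal_masks,
            dict(self.provenance),
        )

    def subset_features(self, feature_idx: list[np.ndarray]) -> "MultiViewDataset":
        masks = None
        if self.signal_masks is not None:
            masks = [m[np.asarray(ix)] for m, ix in zip(self.signal_masks, feature_idx)]
        return MultiViewDataset(
            [X[:, np.asarray(ix)] for X, ix in zip(self.views, feature_idx)],
            self.labels,
            masks,
            dict(self.provenance),
        )


@dataclass(frozen=True)
class SimSetting:
    """Dimensions and fixed constants of one nonlinear simulation setting."""

    name: str
    n1: int
    n2: int
    p1: int
    p2: int
    noise_scale: float = 0.2
    signal_fraction: float = 0.10
    theta_max_over_pi: float = 3.0
    theta_jitter: float = 0.5

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def n_signal(self) -> int:
        return int(np.floor(self.signal_fraction * self.p1))


SETTINGS: dict[str, SimSetting] = {
    "S1": SimSetting("S1", n1=200, n2=150, p1=500, p2=500),
    "S2": SimSetting("S2", n1=3000, n2=2250, p1=500, p2=500),
    "S3": SimSetting("S3", n1=200, n2=150, p1=2000, p2=2000),
    "S4": SimSetting("S4", n1=3000, n2=2250, p1=2000, p2=2000),
}


def generate_nonlinear(setting: SimSetting | str, seed: int = 0,
                       keep_intermediates: bool = False) -> MultiViewDataset:
    """Generate one dataset from a nonlinear spiral setting.

    With ``keep_intermediates`` the provenance dict stores the pre-noise
    building blocks (theta, the masked view-1 signal, the clipped and
    normalized view-2 base) for construction-step checks.
    """
    if isinstance(setting, str):
        setting = SETTINGS[setting]
    rng = np.random.default_rng(seed)
    n, p1, p2 = setting.n, setting.p1, setting.p2
    n_sig = setting.n_signal

    theta_grid = np.linspace(0.0, setting.theta_max_over_pi * np.pi, n)
    theta = theta_grid + setting.theta_jitter * rng.uniform(size=n)

    X1_tilde = rng.standard_normal((n, p1))
    sin_curve = np.exp(0.15 * theta) * np.sin(1.5 * theta)
    cos_curve = np.exp(0.15 * theta) * np.cos(1.5 * theta)
    X1_tilde[:, :5] = sin_curve[:, None]
    X1_tilde[:, 5:n_sig] = cos_curve[:, None]

    W = np.zeros((n, p1))
    W[:, :n_sig] = 1.0
    X1 = X1_tilde * W + setting.noise_scale * rng.standard_normal((n, p1))

    # view 2: clip negatives, unit column norm, add U(0,1) noise per entry
    base = np.clip(X1[:, :p2], 0.0, None)
    norms = np.linalg.norm(base, axis=0)
    norms = np.where(norms < 1e-12, 1.0, norms)
    base = base / norms
    X2 = base + rng.uniform(size=(n, p2))

    labels = np.concatenate([np.ones(setting.n1, dtype=int),
                             np.full(setting.n2, 2, dtype=int)])
    perm = rng.permutation(n)
    provenance = {"setting": setting.name, "seed": seed}
    if keep_intermediates:
        provenance["theta"] = theta
        provenance["theta_grid"] = theta_grid
        provenance["view2_base"] = base[perm]
        provenance["permutation"] = perm
    masks = [np.zeros(p1, dtype=bool), np.zeros(p2, dtype=bool)]
    masks[0][:n_sig] = True
    return MultiViewDataset(
        views=[X1[perm], X2[perm]],
        labels=labels[perm],
        signal_masks=masks,
        provenance=provenance,
    )


def generate_linear_toy(n_per_class: int = 20, p: int = 5, gap: float = 10.0,
                        seed: int = 0) -> MultiViewDataset:
    """Two Gaussian class clouds sharing a latent factor across two views.

    A fast sanity fixture: at large ``gap`` the classes are perfectly
    separable in either view; at ``gap = 0`` labels are uninformative.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.repeat([1, 2], n_per_class)
    z = rng.standard_normal(n)  # shared latent factor
    shift = np.where(labels == 1, -gap / 2, gap / 2)
    views = []
    for _ in range(2):
        load = rng.standard_normal(p)
        X = (
            np.outer(z, load)
            + shift[:, None]
            + rng.standard_normal((n, p))
        )
        views.append(X)
    perm = rng.permutation(n)
    return MultiViewDataset(
        [X[perm] for X in views],
        labels[perm],
        None,
        {"setting": "linear_toy", "seed": seed, "gap": gap},
    )


def monte_carlo_replicates(setting: SimSetting | str, n_reps: int,
                           base_seed: int = 0):
    """Independent (train, validation, test) triples for one setting."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    out = []
    for child in ss.spawn(n_reps):
        s_train, s_val, s_test = [int(c.generate_state(1)[0] % (2**31))
                                  for c in child.spawn(3)]
        out.append((
            generate_nonlinear(setting, seed=s_train),
            generate_nonlinear(setting, seed=s_val),
            generate_nonlinear(setting, seed=s_test),
        ))
    return out


# ---------------------------------------------------------------------------
# on-disk format: CSV per view + labels + masks + manifest
# ---------------------------------------------------------------------------

def write_dataset(dataset: MultiViewDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"sample_{i}" for i in range(dataset.n_samples)]
    for d, X in enumerate(dataset.views):
        df = pd.DataFrame(X, index=sample_ids,
                          columns=[f"v{d + 1}_f{j}" for j in range(X.shape[1])])
        df.to_csv(outdir / f"view{d + 1}.csv", index_label="sample_id")
    pd.DataFrame({"sample_id": sample_ids, "label": dataset.labels}).to_csv(
        outdir / "labels.csv", index=False
    )
    if dataset.signal_masks is not None:
        for d, mask in enumerate(dataset.signal_masks):
            pd.DataFrame({
                "feature": [f"v{d + 1}_f{j}" for j in range(len(mask))],
                "is_signal": mask.astype(int),
            }).to_csv(outdir / f"signal_mask_view{d + 1}.csv", index=False)
    manifest = {
        "n_views": dataset.n_views,
        "n_samples": dataset.n_samples,
        "view_dims": [int(X.shape[1]) for X in dataset.views],
        "provenance": {k: v for k, v in dataset.provenance.items()
                       if isinstance(v, (str, int, float))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(view_paths, label_path, mask_paths=None) -> MultiViewDataset:
    """Load row-aligned views + labels from CSV, verifying sample IDs."""
    views, ids = [], None
    for path in view_paths:
        df = pd.read_csv(path, index_col=0)
        if ids is None:
            ids = df.index
        elif not df.index.equals(ids):
            raise ValueError(f"sample IDs in {path} do not match the first view")
        views.append(df.to_numpy(dtype=float))
    ldf = pd.read_csv(label_path)
    if "sample_id" in ldf.columns:
        ldf = ldf.set_index("sample_id").loc[ids]
    labels = ldf["label"].to_numpy()
    masks = None
    if mask_paths:
        masks = [pd.read_csv(p)["is_signal"].to_numpy().astype(bool)
                 for p in mask_paths]
    return MultiViewDataset(views, labels, masks, {"source": "csv"})
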