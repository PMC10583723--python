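"""Post-allocation randomization and sample-manifest I/O.

An incidence matrix only fixes *how many* subjects of each treatment go
in each batch.  Turning it into a processing plan for named samples
takes three randomization steps, applied in order:

1. :func:`permute_batches` — shuffle the batch order (the heuristic
   fills batches in a fixed order, which must not leak into run order);
2. :func:`assign_subjects` — within each treatment, assign the actual
   samples to that treatment's batch slots uniformly at random;
3. :func:`order_within_batches` — shuffle the processing order inside
   each batch.

None of the steps changes the batch compositions, so the D-criterion of
the plan equals that of the allocation it came from.

Manifests are CSV files with columns ``sample_id,treatment``; plans are
CSV with ``sample_id,treatment,batch,position`` (1-based, lab
convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ManifestMismatchError
from .problem import AllocationProblem

__all__ = [
    "make_processing_plan",
    "read_manifest",
    "validate_manifest",
    "permute_batches",
    "assign_subjects",
    "order_within_batches",
    "incidence_from_plan",
    "write_incidence",
    "read_incidence",
]

MANIFEST_COLUMNS = ["sample_id", "treatment"]
PLAN_COLUMNS = ["sample_id", "treatment", "batch", "position"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV (columns ``sample_id,treatment``)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestMismatchError(f"manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ManifestMismatchError(f"duplicate sample_ids: {dups}")
    return df[MANIFEST_COLUMNS]


def validate_manifest(manifest: pd.DataFrame, problem: AllocationProblem) -> None:
    """Check that manifest per-treatment counts equal the problem's cohort."""
    counts = manifest["treatment"].value_counts().to_dict()
    expected: Mapping[str, int] = dict(
        zip(problem.treatment_labels, problem.t.tolist())
    )
    if counts != expected:
        raise ManifestMismatchError(
            f"manifest counts {counts} do not match problem counts {dict(expected)}"
        )


def permute_batches(incidence: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Return the incidence with its batch rows uniformly permuted.

    Equivalent to premultiplying by a random permutation matrix; the
    D-criterion is invariant to batch order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = np.asarray(incidence)
    return N[rng.permutation(N.shape[0])].copy()


def assign_subjects(
    incidence: np.ndarray,
    manifest: pd.DataFrame,
    treatment_labels: tuple[str, ...] | list[str],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Assign named samples to the incidence's slots, uniformly per treatment.

    Slots are enumerated batch-major; each treatment's samples are
    shuffled and dealt into its slots.  Positions within a batch are
    provisional (slot order) until :func:`order_within_batches`.

    Raises
    ------
    ManifestMismatchError
        If manifest counts disagree with the incidence column sums.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = np.asarray(incidence, dtype=int)
    B, T = N.shape
    labels = list(treatment_labels)
    counts = manifest["treatment"].value_counts().to_dict()
    expected = {labels[i]: int(N[:, i].sum()) for i in range(T)}
    if {k: v for k, v in counts.items()} != expected:
        raise ManifestMismatchError(
            f"manifest counts {counts} do not match allocation counts {expected}"
        )

    # shuffled sample queue per treatment
    queues: dict[str, list[str]] = {}
    for lab in labels:
        ids = manifest.loc[manifest["treatment"] == lab, "sample_id"].tolist()
        order = rng.permutation(len(ids))
        queues[lab] = [ids[j] for j in order]

    rows = []
    for k in range(B):
        position = 1
        for i in range(T):
            for _ in range(N[k, i]):
                rows.append(
                    {
                        "sample_id": queues[labels[i]].pop(),
                        "treatment": labels[i],
                        "batch": k + 1,
                        "position": position,
                    }
                )
                position += 1
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def order_within_batches(
    plan: pd.DataFrame, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Shuffle processing positions independently within each batch.

    Batch compositions are untouched; positions remain ``1..b_k``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = plan.copy()
    for batch, idx in out.groupby("batch").groups.items():
        idx = list(idx)
        out.loc[idx, "position"] = rng.permutation(len(idx)) + 1
    return out.sort_values(["batch", "position"], ignore_index=True)


def incidence_from_plan(
    plan: pd.DataFrame, treatment_labels: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Rebuild the B x T incidence matrix from a processing plan."""
    labels = list(treatment_labels)
    B = int(plan["batch"].max())
    N = np.zeros((B, len(labels)), dtype=int)
    col = {lab: i for i, lab in enumerate(labels)}
    for _, row in plan.iterrows():
        N[int(row["batch"]) - 1, col[row["treatment"]]] += 1
    return N


def make_processing_plan(
    problem: AllocationProblem,
    manifest: pd.DataFrame,
    seed: int,
    algorithm: str = "sba",
    best_of: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: allocate, then the three randomization steps.

    Picks the best of ``best_of`` allocations, shuffles the batch order,
    assigns the manifest's samples to slots, and randomizes the
    processing order within each batch.  Returns the plan plus a
    provenance record (algorithm, seeds, score) sufficient to reproduce
    it.
    """
    from .experiments import best_of_n  # local import to keep module layering flat

    validate_manifest(manifest, problem)
    best = best_of_n(problem, algorithm, best_of, seed)
    rng = np.random.default_rng([int(seed), 0xB10C])  # post-hoc randomization stream
    shuffled = permute_batches(best.incidence, rng)
    plan = assign_subjects(shuffled, manifest, problem.treatment_labels, rng)
    plan = order_within_batches(plan, rng)
    provenance = {
        "algorithm": best.algorithm,
        "best_of": int(best_of),
        "master_seed": int(seed),
        "allocation_seed": best.seed,
        "d_score": best.d_score,
        "confounded": best.confounded,
        "treatments": dict(zip(problem.treatment_labels, problem.t.tolist())),
        "batch_sizes": problem.b.tolist(),
    }
    return plan, provenance


def write_incidence(
    path: str | Path, incidence: np.ndarray, treatment_labels: tuple[str, ...] | list[str]
) -> None:
    """Write an incidence matrix as a batches x treatments CSV."""
    N = np.asarray(incidence, dtype=int)
    df = pd.DataFrame(N, columns=list(treatment_labels))
    df.insert(0, "batch", range(1, N.shape[0] + 1))
    df.to_csv(path, index=False)


def read_incidence(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an incidence CSV written by :func:`write_incidence`.

    Returns the B x T matrix and the treatment labels (column header).
    A leading ``batch`` column, if present, is dropped.
    """
    df = pd.read_csv(path)
    if "batch" in df.columns:
        df = df.drop(columns=["batch"])
    labels = [str(c) for c in df.columns]
    return df.to_numpy(dtype=int), labels
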