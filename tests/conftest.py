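import numpy as np
import pandas as pd
import pytest

import genecalib as gc


@pytest.fixture(scope="session")
def registry():
    return gc.load_default_registry()


@pytest.fixture(scope="session")
def synthetic_world(registry):
    """A clean, well-separated synthetic benchmark at the default class sizes."""
    cfg = gc.SyntheticConfig(seed=7, missing_rate=0.0)
    return gc.generate_dataset(cfg, registry)


def make_variant_table(rows):
    """Build a native-column variant table from (id, label, sources, assertion,
    protein_pos) tuples."""
    recs = []
    for vid, label, sources, assertion, ppos in rows:
        chrom, pos, ref, alt = vid.split(":")
        recs.append(
            dict(
                variant_id=vid, chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                protein_pos=ppos, aa_ref="A", aa_alt="V",
                label=label, sources=sources, assertion=assertion,
            )
        )
    df = pd.DataFrame(recs)
    df["pos"] = df["pos"].astype("Int64")
    df["protein_pos"] = pd.array(
        [p if p is not None else pd.NA for p in df["protein_pos"]], dtype="Int64"
    )
    return df


@pytest.fixture
def ascending_spec():
    return gc.ToolSpec("toy", "ascending", "inclusive", 0.5, 0.0, 1.0)


@pytest.fixture
def ascending_strict_spec():
    return gc.ToolSpec("toy_strict", "ascending", "strict", 0.5, 0.0, 1.0)


def random_instance(rng, n_max=200):
    """A random labeled score set for sweep-oracle comparisons: random class
    sizes, random separation, ties induced by rounding, random semantics."""
    n_pos = int(rng.integers(1, n_max // 2))
    n_neg = int(rng.integers(1, n_max // 2))
    shift = rng.uniform(0, 2)
    scores = np.concatenate(
        [rng.normal(shift, 1, n_pos), rng.normal(0, 1, n_neg)]
    )
    if rng.random() < 0.5:  # induce tied scores
        scores = np.round(scores, 1)
    labels = np.array(["disease"] * n_pos + ["neutral"] * n_neg, dtype=object)
    spec = gc.ToolSpec(
        "rand",
        direction=str(rng.choice(["ascending", "descending"])),
        comparison=str(rng.choice(["strict", "inclusive"])),
        default_threshold=float(rng.uniform(-1, 2)),
    )
    return scores, labels, spec


def brute_force_sweep(scores, labels, spec):
    """O(n^2) threshold oracle: re-derive predictions and MCC from scratch at
    every candidate (distinct scores plus sentinels), independent of the
    package's sweep implementation."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object) == "disease"
    cand = np.unique(scores)
    cand = np.concatenate(([cand[0] - 1], cand, [cand[-1] + 1]))
    best = (-2.0, None)
    curve = []
    for t in cand:
        if spec.direction == "ascending":
            pred = scores >= t if spec.comparison == "inclusive" else scores > t
        else:
            pred = scores <= t if spec.comparison == "inclusive" else scores < t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum())
        tn = int((~pred & ~y).sum())
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
        curve.append((t, mcc))
        if mcc > best[0]:
            best = (mcc, t)
    return best[0], curve
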