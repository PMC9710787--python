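import numpy as np
import pandas as pd
import pytest

import timsfeat as tf


def make_cloud(df_rows):
    """PointCloud from a list of (frame_id, rt, scan, inv_k0, mz, intensity)."""
    df = pd.DataFrame(
        df_rows, columns=["frame_id", "rt", "scan", "inv_k0", "mz", "intensity"]
    )
    return tf.PointCloud(df)


@pytest.fixture(scope="session")
def small_truths():
    return tf.make_benchmark_truths(n=5, seed=7)


@pytest.fixture(scope="session")
def small_cloud(small_truths):
    cloud, manifest = tf.generate_dataset(small_truths, seed=7)
    return cloud, manifest


@pytest.fixture(scope="session")
def benchmark_run():
    """The standard synthetic benchmark: 50 planted features, default noise,
    seed 1, detected at a queue threshold of 100 counts."""
    truths = tf.make_benchmark_truths(n=50, seed=1)
    cloud, manifest = tf.generate_dataset(truths, seed=1)
    cfg = tf.RunConfig(min_voxel_intensity=100.0)
    features = tf.detect_features(cloud, cfg)
    return cloud, manifest, features


def match_to_truth(features, manifest, tol_ppm=10.0, tol_scans=20, tol_rt=5.0):
    """Greedy truth-to-detection matching used by recovery checks."""
    used = set()
    matches = []
    for _, t in manifest.iterrows():
        best = None
        for j, f in enumerate(features):
            if j in used:
                continue
            ppm = abs(f.mono_mz - t.mono_mz) / t.mono_mz * 1e6
            if (
                ppm <= tol_ppm
                and abs(f.scan_apex - t.scan_apex) <= tol_scans
                and abs(f.rt_apex - t.rt_apex) <= tol_rt
            ):
                if best is None or ppm < best[1]:
                    best = (j, ppm)
        if best is not None:
            used.add(best[0])
            matches.append((t, features[best[0]], best[1]))
    return matches


def random_features(rng, n, mz_range=(400.0, 1000.0), scored=True):
    """Random but invariant-respecting Feature objects for oracle tests."""
    out = []
    for _ in range(n):
        mono = float(rng.uniform(*mz_range))
        rt_apex = float(rng.uniform(50, 550))
        scan_apex = int(rng.integers(50, 750))
        out.append(
            tf.Feature(
                mono_mz=mono,
                charge=int(rng.integers(1, 5)),
                intensity=float(rng.uniform(1e3, 1e6)),
                rt_apex=rt_apex,
                rt_lo=rt_apex - 5,
                rt_hi=rt_apex + 5,
                scan_apex=scan_apex,
                scan_lo=scan_apex - 30,
                scan_hi=scan_apex + 30,
                num_isotopes=int(rng.integers(3, 7)),
                deconvolution_score=float(rng.uniform(20, 2000)),
                coelution_coefficient=float(rng.uniform(0, 1)),
                mobility_coefficient=float(rng.uniform(0, 1)),
                identifiability_score=float(rng.uniform(0, 1)) if scored else None,
                inv_k0_apex=float(1.6 - 0.001 * scan_apex),
            )
        )
    return out
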