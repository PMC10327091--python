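"""Shared fixtures: a small noise-free community experiment reused across
module tests, plus an independent brute-force alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import virocell as vc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# brute-force ungapped alignment oracle (independent of the seeded searcher)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_align(query: str, subject: str, match=1, mismatch=-2, min_raw=22):
    """Exhaustive scan over every strand, diagonal and (start, end) segment.

    Returns (raw, strand, q_start, q_end, s_start, s_end) of the best
    ungapped segment with query coordinates mapped to the forward query,
    or None when the best raw score is below ``min_raw``. Ties resolve
    toward lower subject start, then '+' strand, then lower query start
    (in alignment orientation), then the shorter segment.
    """
    if not query or not subject:
        return None
    best = None
    lq, ls = len(query), len(subject)
    for strand_idx, strand in enumerate("+-"):
        q = query if strand == "+" else _revcomp(query)
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        sa = np.frombuffer(subject.encode(), dtype=np.uint8)
        n_code = ord("N")
        for d in range(-(lq - 1), ls):
            i = max(0, -d)
            limit = min(lq, ls - d)
            if limit <= i:
                continue
            qs = qa[i:limit]
            ss = sa[i + d : limit + d]
            eq = (qs == ss) & (qs != n_code) & (ss != n_code)
            scores = np.where(eq, match, mismatch)
            cs = np.concatenate(([0], np.cumsum(scores)))
            # score of [a, b) is cs[b]-cs[a]; enumerate the full triangle
            mat = cs[None, :] - cs[:, None]
            a_idx, b_idx = np.triu_indices(len(cs), k=1)
            raws = mat[a_idx, b_idx]
            top = raws.max()
            if best is not None and -top > best[0][0]:
                continue
            for a, b in zip(a_idx[raws == top], b_idx[raws == top]):
                q0 = i + int(a)
                end = i + int(b)
                key = (-int(top), q0 + d, strand_idx, q0, end - q0)
                if best is None or key < best[0]:
                    if strand == "+":
                        oq0, oq1 = q0, end
                    else:
                        oq0, oq1 = lq - end, lq - q0
                    best = (key, (int(top), strand, oq0, oq1, q0 + d, end + d))
    if best is None or best[1][0] < min_raw:
        return None
    return best[1]


@pytest.fixture(scope="session")
def oracle_align():
    return brute_force_align


# ---------------------------------------------------------------------------
# small noise-free community

@pytest.fixture(scope="session")
def small_config() -> vc.CommunityConfig:
    return vc.default_config(
        n_cells=30,
        reads_per_cell=("fixed", 1200),
        ambient_viral_rate=0.0,
        doublet_rate=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_refs(small_config):
    return vc.simulate_references(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_refs):
    reads, truth = vc.simulate_experiment(small_refs, small_config)
    return reads, truth


@pytest.fixture(scope="session")
def small_pipeline(small_config, small_refs, small_experiment):
    reads, _truth = small_experiment
    return vc.run_pair_pipeline(
        reads, small_refs, dominant_family=small_config.dominant_family
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_917)
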