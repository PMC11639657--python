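"""Programmatic example datasets (all synthetic, generated on demand).

``moyamoya_like`` emulates the structure of a bilateral cerebral-angiopathy
severity study: each patient (cluster) contributes an ordinal severity grade
1-3 per hemisphere, patients fall into four smoking-status groups of sizes
(12, 9, 21, 6), and the two hemispheres of a patient are positively
dependent.  The values are synthetic draws, not the clinical data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ClusteredDesign, build_design
from .simulate import get_model, gen_sample, gen_cluster_sizes, gen_group_sizes

__all__ = ["toy_design", "toy_frame", "moyamoya_like", "model_table_draw", "fixture_frame"]


def toy_design() -> ClusteredDesign:
    """Two groups, clusters {(1, 3)} and {(4)}; unweighted effects (1/4, 3/4)."""
    return build_design([("g1", "c1", 1.0), ("g1", "c1", 3.0), ("g2", "c1", 4.0)])


def toy_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"group": ["g1", "g1", "g2"], "cluster": ["c1", "c1", "c1"], "value": [1.0, 3.0, 4.0]}
    )


_MOYA_GROUPS = {1: 12, 2: 9, 3: 21, 4: 6}
# synthetic grade probabilities per smoking group (grades 1..3)
_MOYA_PROBS = {
    1: (0.25, 0.40, 0.35),
    2: (0.40, 0.40, 0.20),
    3: (0.35, 0.40, 0.25),
    4: (0.35, 0.35, 0.30),
}
_MOYA_RHO = 0.5  # latent inter-hemisphere correlation


def moyamoya_like(seed: int = 0) -> pd.DataFrame:
    """Synthetic bilateral ordinal dataset: 48 patients x 2 hemispheres.

    Grades are drawn from a latent bivariate normal with correlation 0.5 cut
    at group-specific thresholds, giving correlated ordinal values in
    {1, 2, 3}.  Long format with columns (group, cluster, value).
    """
    rng = np.random.default_rng(seed)
    rows = []
    pat = 0
    for g, n in _MOYA_GROUPS.items():
        p = np.asarray(_MOYA_PROBS[g])
        thr = norm.ppf(np.cumsum(p)[:-1])
        L = np.linalg.cholesky(np.array([[1.0, _MOYA_RHO], [_MOYA_RHO, 1.0]]))
        for _ in range(n):
            pat += 1
            z = L @ rng.standard_normal(2)
            grades = 1 + np.searchsorted(thr, z)
            for hemi in range(2):
                rows.append({"group": g, "cluster": f"p{pat:02d}", "value": int(grades[hemi])})
    return pd.DataFrame(rows)


def model_table_draw(name: str, d: int = 3, n: int = 20, m: int = 4,
                     seed: int = 0, r: float = 0.0) -> pd.DataFrame:
    """One long-format draw from a named simulation model."""
    model = get_model(name)
    rng = np.random.default_rng(seed)
    n_vec = gen_group_sizes(model.group_imbalance, n, d, rng)
    sizes = [gen_cluster_sizes(model.cluster_imbalance, m, int(ni), rng) for ni in n_vec]
    design = gen_sample(model, d, n_vec, sizes, rng, r=r)
    rows = []
    for gi, g in enumerate(design.groups):
        for j, vec in enumerate(design.clusters[gi]):
            for v in vec:
                rows.append({"group": g, "cluster": f"g{g}c{j + 1}", "value": float(v)})
    return pd.DataFrame(rows)


def fixture_frame(kind: str, seed: int = 0) -> pd.DataFrame:
    """Dispatch for the CLI fixture generator."""
    if kind == "moyamoya_like":
        return moyamoya_like(seed)
    if kind == "toy":
        return toy_frame()
    if kind == "model_table3":
        return model_table_draw("1.1", seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
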