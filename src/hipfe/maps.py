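"""Node-wise anatomical maps of cortical parameters.

Compares cortical thickness (CTh), cortical surface BMD (sBMD) and local
cortical vBMD (= sBMD / CTh) between a fracture group and controls at every
vertex of the canonical periosteal mesh, producing relative and absolute
difference maps with an uncorrected per-vertex significance mask
(non-significant vertices are conventionally rendered white).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

PARAMETERS = ("cth", "sbmd", "ct_vbmd")


@dataclass
class NodewiseMap:
    parameter: str
    mean_control: np.ndarray
    mean_case: np.ndarray
    rel_diff_percent: np.ndarray   # 100 * (case - control) / control
    abs_diff: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray        # p <= alpha, no multiplicity correction
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex_id": np.arange(len(self.p_value)),
            "mean_control": self.mean_control,
            "mean_case": self.mean_case,
            "rel_diff_percent": self.rel_diff_percent,
            "abs_diff": self.abs_diff,
            "p_value": self.p_value,
            "significant": self.significant.astype(int),
        })


def local_ct_vbmd(sbmd_map: np.ndarray, cth_map: np.ndarray) -> np.ndarray:
    """Local cortical vBMD (mg/cm^3) from sBMD (mg/cm^2) and CTh (mm).

    Vertices with non-positive thickness are masked (NaN).
    """
    sbmd = np.asarray(sbmd_map, float)
    cth = np.asarray(cth_map, float)
    out = np.full(np.broadcast(sbmd, cth).shape, np.nan)
    ok = cth > 0
    out[ok] = np.broadcast_to(sbmd, out.shape)[ok] / \
        (np.broadcast_to(cth, out.shape)[ok] / 10.0)
    return out


def nodewise_compare(case_maps: np.ndarray, control_maps: np.ndarray,
                     parameter: str, alpha: float = 0.05,
                     test: str = "welch", fdr: bool = False) -> NodewiseMap:
    """Per-vertex two-sided comparison between cases and controls.

    ``case_maps``/``control_maps`` are (n_subjects, n_vertices) arrays on
    the canonical mesh (identical vertex count and ordering).  The default
    per-vertex test is Welch's t; a Mann-Whitney alternative is available.
    No multiplicity correction is applied unless ``fdr=True``
    (Benjamini-Hochberg).
    """
    a = np.asarray(case_maps, float)
    b = np.asarray(control_maps, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("maps must be (n_subjects, n_vertices) with equal vertex counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")

    mean_case = np.nanmean(a, axis=0)
    mean_control = np.nanmean(b, axis=0)
    if test == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, float)
    elif test == "mannwhitney":
        p = np.array([sps.mannwhitneyu(a[:, v], b[:, v],
                                       alternative="two-sided").pvalue
                      for v in range(a.shape[1])])
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(np.isfinite(p), p, 1.0)
    if fdr:
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, alpha=alpha, method="fdr_bh")[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean_control > 0,
                       100.0 * (mean_case - mean_control) / mean_control, np.nan)
    return NodewiseMap(
        parameter=parameter,
        mean_control=mean_control, mean_case=mean_case,
        rel_diff_percent=rel, abs_diff=mean_case - mean_control,
        p_value=p, significant=p <= alpha, alpha=alpha)


def write_map_ply(mesh, nmap: NodewiseMap, path):
    """Write the canonical mesh as ASCII PLY with per-vertex map scalars."""
    import trimesh
    out = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                          process=False)
    out.vertex_attributes["rel_diff_percent"] = \
        np.nan_to_num(nmap.rel_diff_percent).astype(np.float32)
    out.vertex_attributes["abs_diff"] = \
        np.nan_to_num(nmap.abs_diff).astype(np.float32)
    out.vertex_attributes["p_value"] = nmap.p_value.astype(np.float32)
    out.vertex_attributes["significant"] = nmap.significant.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(trimesh.exchange.ply.export_ply(out, encoding="ascii",
                                                 include_attributes=True))


def render_map(mesh, nmap: NodewiseMap, path, view=("x", "z")):
    """Render a color-mapped projection of the relative-difference map;
    vertices without significant differences are printed white."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    axes = {"x": 0, "y": 1, "z": 2}
    u, v = axes[view[0]], axes[view[1]]
    verts = np.asarray(mesh.vertices)
    vals = np.where(nmap.significant, nmap.rel_diff_percent, np.nan)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(verts[:, u], verts[:, v], c="0.92", s=4, linewidths=0)
    sig = nmap.significant & np.isfinite(vals)
    sc = ax.scatter(verts[sig, u], verts[sig, v], c=vals[sig], s=5,
                    cmap="RdBu", linewidths=0)
    fig.colorbar(sc, ax=ax, label=f"{nmap.parameter} difference (%)")
    ax.set_aspect("equal")
    ax.set_xlabel(view[0] + " (mm)")
    ax.set_ylabel(view[1] + " (mm)")
    fig.savefig(path, dpi=110)
    plt.close(fig)
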