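"""Seeded generators for every input type, with ground truth.

Each generator is a pure function of its parameters and seed, emulating the
study's inputs at desk scale:

* multinomial per-individual cluster counts with site-dependent proportions
  (thymoma vs peripheral blood);
* skewed clone-size repertoires (geometric or zipf) with V/J segment usage;
* a tissue x gene mean-TPM table with tissue-restricted expression spikes on
  a log-normal background (GTEx-like);
* a cells x genes log-expression matrix with a gene-module up-shift in one
  cluster on a log-normal noise floor;
* brightfield IHC images built in optical-density space as Gaussian dye
  depositions mixed by Beer--Lambert, with known nucleus positions and
  stain-positivity labels.

Defaults mirror the study conditions: 4 thymoma and 2 blood individuals with
a few thousand cells each, 8 clusters, a 30-tissue expression table, and
well-separated nuclei (minimum separation >= 4 blob sigma) in images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import anndata as ad

from .ihc import StainMatrix, default_hdab_purple, od_to_rgb

__all__ = [
    "CompositionTruth",
    "ImageTruth",
    "default_composition_truth",
    "gen_cell_counts",
    "gen_repertoire",
    "gen_tissue_expression",
    "gen_expression_matrix",
    "gen_ihc_image",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CompositionTruth:
    """True per-site cluster proportions and per-individual cell totals."""

    proportions: Mapping[str, np.ndarray]  # site -> (n_clusters,) probabilities
    totals: Mapping[str, Sequence[int]]  # site -> per-individual cell totals
    clusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n_clusters = None
        for site, p in self.proportions.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions for site {site!r} sum to {p.sum()}, not 1")
            if np.any(p < 0):
                raise ValueError(f"negative proportion for site {site!r}")
            if n_clusters is None:
                n_clusters = p.size
            elif p.size != n_clusters:
                raise ValueError("sites disagree on the number of clusters")
        for site, tot in self.totals.items():
            if site not in self.proportions:
                raise ValueError(f"totals given for unknown site {site!r}")
            if any(t < 0 for t in tot):
                raise ValueError("cell totals must be non-negative")
        if self.clusters and n_clusters is not None and len(self.clusters) != n_clusters:
            raise ValueError("cluster names do not match proportion length")

    @property
    def cluster_names(self) -> tuple[str, ...]:
        if self.clusters:
            return self.clusters
        n = len(next(iter(self.proportions.values())))
        return tuple(f"cluster_{i}" for i in range(n))


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth emitted with a synthetic IHC image."""

    coordinates: np.ndarray  # (n, 2) float (row, col)
    dab_positive: np.ndarray  # (n,) bool
    purple_positive: np.ndarray  # (n,) bool
    stain_matrix: StainMatrix
    blob_sigma: float

    def to_dict(self) -> dict:
        return {
            "coordinates": self.coordinates.tolist(),
            "dab_positive": self.dab_positive.astype(bool).tolist(),
            "purple_positive": self.purple_positive.astype(bool).tolist(),
            "stain_matrix": self.stain_matrix.vectors.tolist(),
            "blob_sigma": self.blob_sigma,
        }


def default_composition_truth(
    n_clusters: int = 8,
    delta_cluster: int = 0,
    delta: float = 0.0,
    n_thymus: int = 4,
    n_blood: int = 2,
    cells_thymus: int = 8000,
    cells_blood: int = 15000,
) -> CompositionTruth:
    """Study-condition truth: equal baseline proportions with an optional
    shift ``delta`` added to one cluster's thymus proportion."""
    base = np.full(n_clusters, 1.0 / n_clusters)
    thymus = base.copy()
    thymus[delta_cluster] += delta
    if thymus[delta_cluster] >= 1.0 or thymus[delta_cluster] < 0.0:
        raise ValueError("delta pushes the target proportion outside [0, 1)")
    others = [i for i in range(n_clusters) if i != delta_cluster]
    thymus[others] = (1.0 - thymus[delta_cluster]) / len(others)
    return CompositionTruth(
        proportions={"thymus": thymus, "blood": base},
        totals={"thymus": [cells_thymus] * n_thymus, "blood": [cells_blood] * n_blood},
    )


def gen_cell_counts(truth: CompositionTruth, seed: int = 0) -> pd.DataFrame:
    """Per-individual multinomial cluster counts.

    Returns a tidy frame with columns ``individual``, ``site`` and one column
    per cluster; each row is one individual's multinomial draw with its
    site's true proportions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for site in sorted(truth.proportions):
        p = np.asarray(truth.proportions[site], dtype=float)
        for i, total in enumerate(truth.totals.get(site, [])):
            rows.append(rng.multinomial(int(total), p))
            index.append((f"{site}_{i}", site))
    counts = pd.DataFrame(rows, columns=list(truth.cluster_names))
    meta = pd.DataFrame(index, columns=["individual", "site"])
    return pd.concat([meta, counts], axis=1)


def _junctions(n: int, rng: np.random.Generator, length: int = 12) -> list[str]:
    """Distinct CDR3-like amino-acid strings (C...F)."""
    seen: set[str] = set()
    out: list[str] = []
    aa = np.array(list(_AA))
    while len(out) < n:
        body = "".join(rng.choice(aa, size=length - 2))
        s = f"C{body}F"
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def gen_repertoire(
    n_clones: int = 1000,
    clone_size_law: tuple[str, float] = ("zipf", 1.5),
    segment_probs: Mapping[str, Mapping[str, float]] | None = None,
    sample_id: str = "S1",
    group: str = "MG",
    chain: str = "TRA",
    seed: int = 0,
) -> pd.DataFrame:
    """AIRR-style clonotype table for one sample.

    Clone sizes follow a geometric or zipf law; ``segment_probs`` maps
    ``"v"``/``"j"`` to segment->probability dicts.
    """
    law, param = clone_size_law
    rng = np.random.default_rng(seed)
    if law == "geometric":
        if not 0.0 < param <= 1.0:
            raise ValueError("geometric parameter must lie in (0, 1]")
        sizes = rng.geometric(param, size=n_clones)
    elif law == "zipf":
        if param <= 1.0:
            raise ValueError("zipf exponent must exceed 1")
        sizes = rng.zipf(param, size=n_clones)
    else:
        raise ValueError(f"unknown clone-size law {law!r}")
    if segment_probs is None:
        segment_probs = {
            "v": {f"TRAV{i}": 1 / 8 for i in range(1, 9)},
            "j": {f"TRAJ{i}": 1 / 8 for i in range(1, 9)},
        }
    out = {}
    for key in ("v", "j"):
        segs = sorted(segment_probs[key])
        p = np.array([segment_probs[key][s] for s in segs], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError(f"{key}-segment probabilities must be a distribution")
        out[key] = rng.choice(segs, size=n_clones, p=p)
    return pd.DataFrame(
        {
            "sequence_id": [f"{sample_id}_{i}" for i in range(n_clones)],
            "sample_id": sample_id,
            "group": group,
            "chain": chain,
            "v_call": out["v"],
            "j_call": out["j"],
            "junction_aa": _junctions(n_clones, rng),
            "duplicate_count": sizes.astype(int),
        }
    )


def gen_tissue_expression(
    n_genes: int = 1000,
    n_tissues: int = 30,
    tra_fraction: float = 0.1,
    tra_tpm_range: tuple[float, float] = (150.0, 1000.0),
    background_tpm_law: tuple[float, float] = (np.log(20.0), 1.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Tissue x gene mean-TPM table with known tissue-restricted genes.

    TRA-labelled genes are expressed in exactly one tissue at a level drawn
    from ``tra_tpm_range``; background genes share a log-normal baseline with
    mild per-tissue jitter. Returns ``(genes x tissues frame, bool labels)``.
    """
    if not 0.0 <= tra_fraction <= 1.0:
        raise ValueError("tra_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    tissues = [f"tissue_{i}" for i in range(n_tissues)]
    n_tra = int(round(tra_fraction * n_genes))
    is_tra = np.zeros(n_genes, dtype=bool)
    is_tra[rng.choice(n_genes, size=n_tra, replace=False)] = True

    mu, sigma = background_tpm_law
    base = rng.lognormal(mu, sigma, size=n_genes)
    jitter = rng.uniform(0.8, 1.25, size=(n_genes, n_tissues))
    expr = base[:, None] * jitter
    for g in np.flatnonzero(is_tra):
        expr[g, :] = 0.0
        expr[g, rng.integers(n_tissues)] = rng.uniform(*tra_tpm_range)
    frame = pd.DataFrame(expr, index=genes, columns=tissues)
    return frame, pd.Series(is_tra, index=genes, name="is_tra")


def gen_expression_matrix(
    n_cells: int = 2000,
    n_genes: int = 1000,
    n_clusters: int = 10,
    module_size: int = 50,
    target_cluster: str = "cluster_0",
    target_cells: int = 200,
    effect_delta: float = 1.0,
    noise: tuple[float, float, float] = (0.0, 0.5, 0.5),
    seed: int = 0,
) -> tuple[ad.AnnData, list[str]]:
    """Cells x genes log-expression matrix with a module up-shift.

    ``noise = (mu_base, sigma_base, sigma_cell)``: per-gene baselines are
    log-normal(mu_base, sigma_base) (the noise floor), per-cell deviations
    Gaussian(0, sigma_cell). Module genes gain ``effect_delta`` (additive on
    the log scale the matrix lives on) in the designated cluster only.

    Returns an :class:`anndata.AnnData` with ``obs["cluster"]`` and the list
    of module gene names.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    mu_base, sigma_base, sigma_cell = noise
    base = rng.lognormal(mu_base, sigma_base, size=n_genes)
    X = base[None, :] + rng.normal(0.0, sigma_cell, size=(n_cells, n_genes))

    others = n_clusters - 1
    sizes = [target_cells] + [(n_cells - target_cells) // others] * others
    sizes[-1] += n_cells - sum(sizes)
    labels = np.repeat(
        [target_cluster] + [f"cluster_{i}" for i in range(1, n_clusters)], sizes
    )
    labels = labels[rng.permutation(n_cells)]

    module = [genes[i] for i in rng.choice(n_genes, size=module_size, replace=False)]
    module_idx = [genes.index(g) for g in module]
    in_target = labels == target_cluster
    X[np.ix_(in_target, module_idx)] += effect_delta

    adata = ad.AnnData(
        X=X.astype(np.float64),
        obs=pd.DataFrame({"cluster": pd.Categorical(labels)},
                         index=[f"cell_{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )
    return adata, module


def _place_nuclei(
    width: int, height: int, n: int, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid placement guaranteeing pairwise separation >= min_sep."""
    margin = min_sep
    jitter = min_sep / 4.0
    spacing = min_sep + 2.0 * jitter
    rows = int((height - 2 * margin) // spacing) + 1
    cols = int((width - 2 * margin) // spacing) + 1
    if rows * cols < n:
        raise ValueError(
            f"cannot place {n} nuclei with separation {min_sep:.1f} px in a "
            f"{height}x{width} image (capacity {rows * cols})"
        )
    cells = rng.choice(rows * cols, size=n, replace=False)
    rr = margin + (cells // cols) * spacing + rng.uniform(-jitter, jitter, size=n)
    cc = margin + (cells % cols) * spacing + rng.uniform(-jitter, jitter, size=n)
    return np.column_stack([rr, cc])


def gen_ihc_image(
    width: int = 512,
    height: int = 512,
    n_nuclei: int = 200,
    p_dab_positive: float = 0.6,
    p_purple_positive: float = 0.6,
    p_double_positive: float = 0.5,
    blob_sigma: float = 3.0,
    stain_matrix: StainMatrix | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, ImageTruth]:
    """Synthetic brightfield IHC image with known positivity labels.

    Every nucleus deposits hematoxylin; DAB/purple deposits follow the joint
    positivity law given by the two marginals and the double-positive
    probability. Dye depositions are isotropic Gaussians of scale
    ``blob_sigma`` summed in optical-density space; the RGB image is
    ``255 * exp(-OD)`` per channel plus optional Gaussian pixel noise.
    """
    p_bc = p_double_positive
    p_b_only = p_dab_positive - p_bc
    p_c_only = p_purple_positive - p_bc
    p_none = 1.0 - p_bc - p_b_only - p_c_only
    for name, p in (("double", p_bc), ("DAB-only", p_b_only),
                    ("purple-only", p_c_only), ("negative", p_none)):
        if p < -1e-12:
            raise ValueError(f"inconsistent positivity law: {name} probability {p:.3f} < 0")
    if stain_matrix is None:
        stain_matrix = default_hdab_purple()
    rng = np.random.default_rng(seed)

    od = np.zeros((height, width, 3), dtype=float)
    if n_nuclei > 0:
        coords = _place_nuclei(width, height, n_nuclei, 4.0 * blob_sigma, rng)
        joint = rng.choice(
            4, size=n_nuclei, p=np.clip([p_bc, p_b_only, p_c_only, p_none], 0.0, None)
        )
        dab = (joint == 0) | (joint == 1)
        purple = (joint == 0) | (joint == 2)

        yy, xx = np.mgrid[0:height, 0:width]
        amplitudes = np.array([1.0, 1.0, 0.8])  # peak OD per stain deposit
        for k in range(n_nuclei):
            r, c = coords[k]
            g = np.exp(-(((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * blob_sigma**2)))
            conc = np.zeros(3)
            conc[0] = amplitudes[0]
            if dab[k]:
                conc[1] = amplitudes[1]
            if purple[k]:
                conc[2] = amplitudes[2]
            od += g[:, :, None] * (conc @ stain_matrix.vectors)[None, None, :]
    else:
        coords = np.empty((0, 2))
        dab = np.empty(0, dtype=bool)
        purple = np.empty(0, dtype=bool)

    img = od_to_rgb(od)
    if noise_sd > 0:
        img = img.astype(float) + rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = ImageTruth(
        coordinates=coords,
        dab_positive=np.asarray(dab, dtype=bool),
        purple_positive=np.asarray(purple, dtype=bool),
        stain_matrix=stain_matrix,
        blob_sigma=blob_sigma,
    )
    return img, truth
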