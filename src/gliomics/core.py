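"""Shared data model for quantitative multiomics layers.

The study design this package targets is a multiplexed (TMT-style)
comparison of tumor groups against a normal-tissue control: three normal
cortex samples, four PDGFRA-driven high-grade-glioma (HGG) samples, and
three NTRK-driven HGG samples quantified in a single 10-plex, alongside a
matched transcriptome (FPKM).  All containers are thin wrappers around
pandas objects so that every stage of the pipeline works on plain
feature-by-sample DataFrames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gliomics")

LAYERS = ("proteome", "phosphoproteome", "transcriptome")

#: canonical group labels of the default study design
CORTEX, PDGFRA, NTRK = "cortex", "PDGFRA", "NTRK"


class GliomicsError(Exception):
    """Base class for package errors."""


class DesignError(GliomicsError):
    """Sample design and data disagree (missing samples, too few groups...)."""


class DataError(GliomicsError):
    """Values violate a contract (negative intensity, bad functional sign...)."""


class FormatError(GliomicsError):
    """A file does not follow the expected dialect."""


class ConfigError(GliomicsError):
    """Invalid configuration (non-positive sizes, inconsistent subsets...)."""


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-group assignment of one multiplexed experiment.

    Parameters
    ----------
    sample_ids : ordered unique sample labels
    groups : group label per sample, aligned with ``sample_ids``
    """

    sample_ids: tuple
    groups: tuple

    def __post_init__(self):
        if len(self.sample_ids) != len(self.groups):
            raise DesignError("sample_ids and groups must align")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DesignError("sample_ids must be unique")
        if len(set(self.groups)) < 2:
            raise DesignError("need at least two groups")

    @classmethod
    def from_groups(cls, group_sizes: dict) -> "SampleDesign":
        """Build a design from ``{group: n_replicates}``; ids are ``group_i``."""
        ids, grp = [], []
        for g, n in group_sizes.items():
            for i in range(1, n + 1):
                ids.append(f"{g}_{i}")
                grp.append(g)
        return cls(tuple(ids), tuple(grp))

    @property
    def group_names(self) -> tuple:
        seen = dict.fromkeys(self.groups)
        return tuple(seen)

    def samples_of(self, group) -> list:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def group_sizes(self) -> dict:
        return {g: len(self.samples_of(g)) for g in self.group_names}

    def require_replicates(self, min_n: int = 2) -> None:
        for g, n in self.group_sizes().items():
            if n < min_n:
                raise DesignError(f"group {g!r} has {n} samples; needs >= {min_n}")

    def to_frame(self) -> pd.DataFrame:
        reps = {}
        rows = []
        for s, g in zip(self.sample_ids, self.groups):
            reps[g] = reps.get(g, 0) + 1
            rows.append((s, g, reps[g]))
        return pd.DataFrame(rows, columns=["sample_id", "group", "replicate_index"])


DEFAULT_DESIGN = SampleDesign.from_groups({CORTEX: 3, PDGFRA: 4, NTRK: 3})


@dataclass
class OmicsMatrix:
    """One quantitative layer: features x samples with its sample design.

    ``scale`` records whether ``data`` holds raw nonnegative intensities
    (``"linear"``) or log2-transformed values (``"log2"``).  All statistics
    downstream operate on the log2 scale.
    """

    layer: str
    data: pd.DataFrame
    design: SampleDesign
    scale: str = "linear"
    n_dropped_missing: int = 0

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise DataError(f"unknown layer {self.layer!r}")
        if set(self.data.columns) != set(self.design.sample_ids):
            raise DesignError("matrix columns do not match design samples")
        # enforce design column order
        self.data = self.data[list(self.design.sample_ids)]
        if self.scale == "linear" and (self.data.values < 0).any():
            raise DataError("negative intensities in linear-scale matrix")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    def log2(self, median_center: bool = True) -> "OmicsMatrix":
        """Log2-transform raw intensities.

        Zeros are floored at half the smallest positive value of the layer
        before logging; TMT columns are then median-centered per sample
        (scale normalization), which removes loading differences and the
        bulk of isobaric ratio compression's offset.
        """
        if self.scale == "log2":
            return self
        vals = self.data.to_numpy(dtype=float)
        pos = vals[vals > 0]
        if pos.size == 0:
            raise DataError("matrix has no positive values to log-transform")
        floor = pos.min() / 2.0
        logv = np.log2(np.maximum(vals, floor))
        if median_center:
            logv = logv - np.median(logv, axis=0, keepdims=True)
        out = pd.DataFrame(logv, index=self.data.index, columns=self.data.columns)
        return OmicsMatrix(self.layer, out, self.design, scale="log2",
                           n_dropped_missing=self.n_dropped_missing)

    def require_log2(self) -> "OmicsMatrix":
        return self if self.scale == "log2" else self.log2()

    def group_means(self) -> pd.DataFrame:
        """Per-group mean of each feature (columns ordered as the design)."""
        m = self.require_log2()
        cols = {g: m.data[m.design.samples_of(g)].mean(axis=1)
                for g in m.design.group_names}
        return pd.DataFrame(cols)

    def subset(self, features) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.data.loc[list(features)], self.design,
                           scale=self.scale, n_dropped_missing=self.n_dropped_missing)


@dataclass
class RelationMap:
    """Directed regulator->target edges.

    Covers kinase->substrate-site links (``site`` set), TF->target-gene links
    (``site`` empty), and functional phosphosite annotations (``sign`` set to
    +1 for tumor-promoting, -1 for tumor-inhibiting phosphorylation).
    """

    kind: str
    edges: pd.DataFrame  # columns regulator, target, site, sign

    KINDS = ("kinase_substrate", "tf_target", "functional_sites")
    COLUMNS = ("regulator", "target", "site", "sign")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise DataError(f"unknown relation kind {self.kind!r}")
        df = self.edges.copy()
        for c in self.COLUMNS:
            if c not in df.columns:
                df[c] = None
        df = df[list(self.COLUMNS)]
        before = len(df)
        df = df.drop_duplicates(subset=["regulator", "target", "site"])
        if len(df) < before:
            logger.info("RelationMap(%s): dropped %d duplicate edges",
                        self.kind, before - len(df))
        if self.kind == "functional_sites":
            signs = pd.to_numeric(df["sign"], errors="coerce")
            if not signs.isin([1, -1]).all():
                raise DataError("functional_sites requires sign in {+1,-1}")
            df["sign"] = signs.astype(int)
        self.edges = df.reset_index(drop=True)

    def __len__(self):
        return len(self.edges)

    def targets_of(self, regulator) -> pd.DataFrame:
        return self.edges[self.edges["regulator"] == regulator]

    def regulators_of(self, target) -> pd.DataFrame:
        return self.edges[self.edges["target"] == target]

    @property
    def regulators(self) -> list:
        return sorted(self.edges["regulator"].unique())


def site_id(protein: str, residue: str, position: int) -> str:
    """Composite phosphosite identity, e.g. ``AKT1_S473``."""
    return f"{protein}_{residue}{int(position)}"


def parse_site_id(sid: str) -> tuple:
    """Split ``PROT_S473`` into (protein, residue, position)."""
    prot, _, tail = sid.rpartition("_")
    if not prot or not tail or tail[0] not in "STY":
        raise DataError(f"not a phosphosite id: {sid!r}")
    return prot, tail[0], int(tail[1:])


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe (pathway definitions from GMT)."""

    sets: dict
    universe: set = field(default_factory=set)

    def __post_init__(self):
        self.sets = {k: set(v) for k, v in self.sets.items()}
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")
            if not members <= self.universe:
                raise DataError(f"gene set {name!r} not contained in universe")

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]
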