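"""Per-species coverage accumulation and the introgression score.

The introgression statistic for a sample is the sum of the mean coverages of
reads assigned to every *non-focal* species of the panel, divided by the mean
coverage of the focal species.  Mean coverage for a species averages depth
over ALL of that species' reference positions, zeros included — the
genome-wide mean, not a covered-bases-only mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import HitTable
from .simulate import ReferencePanel

__all__ = [
    "CoverageProfile",
    "IntrogressionScore",
    "accumulate_coverage",
    "introgression_score",
    "score_study",
    "coverage_long_table",
]

SCORE_COLUMNS = ["sample_id", "genus", "species", "score"]
COVERAGE_COLUMNS = ["sample_id", "genus", "focal_species", "species", "mean_coverage"]


@dataclass
class CoverageProfile:
    """Per-base depth over a genus panel plus per-species mean coverage."""

    genus: str
    depth: dict[tuple[str, str], np.ndarray]  # (species, locus) -> depth array
    mean_cov: dict[str, float]
    per_locus_mean: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (sp, loc), d in self.depth.items():
            rows.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "locus": loc,
                        "position": np.arange(d.size),
                        "depth": d,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.mean_cov), "mean_coverage": list(self.mean_cov.values())}
        )


@dataclass(frozen=True)
class IntrogressionScore:
    sample_id: str
    genus: str
    focal_species: str
    score: float


def accumulate_coverage(
    hits,
    panel: ReferencePanel,
    read_length: int | None = None,
    per_locus_mean: bool = False,
) -> CoverageProfile:
    """Accumulate per-base depth from mapping hits.

    Each hit increments depth over [position, position + read_length).
    ``hits`` is either a :class:`HitTable` (read length implied) or a
    DataFrame with species/locus/position columns plus ``read_length``.
    With ``per_locus_mean`` the species mean averages per-locus means instead
    of pooling all bases; the two agree exactly when loci are equal-length.
    """
    if isinstance(hits, HitTable):
        L = hits.read_length
        li, si, off = hits.index.locate(hits.gstart)
        species_arr = np.asarray(hits.index.species)[si]
        locus_arr = hits.index.locus_names[li]
        pos_arr = off
    else:
        if read_length is None:
            raise ValueError("read_length is required for DataFrame hit input")
        L = int(read_length)
        species_arr = hits["species"].to_numpy()
        locus_arr = hits["locus"].to_numpy()
        pos_arr = hits["position"].to_numpy(dtype=np.int64)

    depth: dict[tuple[str, str], np.ndarray] = {
        (sp, loc): np.zeros(panel.lengths[loc], dtype=np.int64)
        for sp in panel.species
        for loc in panel.locus_ids
    }
    # difference-array trick: +1 at start, -1 past end, then cumsum per locus
    key_df = pd.DataFrame({"species": species_arr, "locus": locus_arr, "pos": pos_arr})
    for (sp, loc), grp in key_df.groupby(["species", "locus"], sort=False, observed=True):
        if (sp, loc) not in depth:
            raise ValueError(f"hit references unknown locus {sp}/{loc}")
        n = panel.lengths[loc]
        p = grp["pos"].to_numpy(dtype=np.int64)
        if (p < 0).any() or (p + L > n).any():
            bad = int(p[(p < 0) | (p + L > n)][0])
            raise ValueError(f"hit at {sp}/{loc}:{bad} extends beyond locus end ({n} bp)")
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, p, 1)
        np.add.at(diff, p + L, -1)
        depth[(sp, loc)] = np.cumsum(diff[:-1])

    mean_cov: dict[str, float] = {}
    for sp in panel.species:
        if per_locus_mean:
            mean_cov[sp] = float(np.mean([depth[(sp, loc)].mean() for loc in panel.locus_ids]))
        else:
            total = sum(int(depth[(sp, loc)].sum()) for loc in panel.locus_ids)
            mean_cov[sp] = total / panel.total_length
    return CoverageProfile(panel.genus, depth, mean_cov, per_locus_mean)


def introgression_score(
    profile_or_meancov,
    focal: str,
    sample_id: str = "",
    genus: str | None = None,
) -> IntrogressionScore:
    """Sum of non-focal mean coverages over the focal mean coverage."""
    if isinstance(profile_or_meancov, CoverageProfile):
        mean_cov = profile_or_meancov.mean_cov
        genus = genus if genus is not None else profile_or_meancov.genus
    else:
        mean_cov = dict(profile_or_meancov)
    if focal not in mean_cov:
        raise ValueError(f"focal species {focal!r} absent from coverage profile")
    focal_cov = mean_cov[focal]
    if focal_cov <= 0:
        raise ValueError(f"focal species unmapped: mean coverage of {focal!r} is 0")
    nonfocal = sum(v for s, v in mean_cov.items() if s != focal)
    return IntrogressionScore(sample_id, genus or "", focal, float(nonfocal / focal_cov))


def score_study(scores) -> pd.DataFrame:
    """Assemble per-sample scores into the table the GLM consumes."""
    rows = [
        {"sample_id": s.sample_id, "genus": s.genus, "species": s.focal_species, "score": s.score}
        for s in scores
    ]
    if not rows:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    df = pd.DataFrame(rows)
    if (df["genus"] == "").any():
        bad = df.loc[df["genus"] == "", "sample_id"].iloc[0]
        raise ValueError(f"sample {bad!r} has unknown genus")
    return df[SCORE_COLUMNS]


def coverage_long_table(entries) -> pd.DataFrame:
    """Long-format per-sample per-species mean coverage.

    ``entries`` iterates (sample_id, genus, focal_species, CoverageProfile or
    mean-coverage mapping).  This is the schema the contamination simulation
    operates on, and the schema accepted from externally produced coverage
    TSVs.
    """
    rows = []
    for sample_id, genus, focal, prof in entries:
        mean_cov = prof.mean_cov if isinstance(prof, CoverageProfile) else dict(prof)
        for sp, v in mean_cov.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "genus": genus,
                    "focal_species": focal,
                    "species": sp,
                    "mean_coverage": float(v),
                }
            )
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)
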