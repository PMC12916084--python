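"""Age-length keys and the survey inclusion filter.

An age-length key (ALK) is a length-bin x age probability table built from
the aged subsample of one survey (one species x lake x year); it is used to
assign ages to the fish that were only measured.  Surveys enter the
analysis only when their aged subsample shows at least 5 distinct age
groups with at least 5 fish each, which guards against keys built from a
handful of fish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgeLengthKey", "build_alk", "apply_alk", "filter_surveys", "SURVEY_KEY"]

SURVEY_KEY = ["species", "lake_id", "year"]


@dataclass
class AgeLengthKey:
    """Per-survey length-bin x age probability matrix.

    ``bin_edges`` are half-open ``[lo, hi)`` boundaries (length B+1);
    ``probs[b, a]`` is the probability a fish in bin ``b`` has ``ages[a]``;
    nonempty rows sum to 1, empty bins are all-NaN.
    """

    species: str
    lake_id: str
    year: int
    bin_edges: np.ndarray
    ages: np.ndarray
    probs: np.ndarray

    def row(self, length: float) -> np.ndarray | None:
        """Probability row for a length, or None if outside the key's range."""
        b = np.searchsorted(self.bin_edges, length, side="right") - 1
        if b < 0 or b >= len(self.bin_edges) - 1:
            return None
        return self.probs[b]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(self.probs.shape[0]):
            for a, age in enumerate(self.ages):
                if np.isfinite(self.probs[b, a]):
                    rows.append(
                        (
                            self.species,
                            self.lake_id,
                            self.year,
                            self.bin_edges[b],
                            self.bin_edges[b + 1],
                            age,
                            self.probs[b, a],
                        )
                    )
        return pd.DataFrame(
            rows, columns=SURVEY_KEY + ["bin_lo", "bin_hi", "age", "prob"]
        )


def build_alk(aged_records: pd.DataFrame, bin_width: float = 1.0) -> AgeLengthKey:
    """Build the key for one survey from its aged records.

    Row for bin b and age a is (aged fish in b with age a) / (aged fish
    in b).  Bins cover [floor(min L), ceil(max L)) in ``bin_width`` steps.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    aged = aged_records.loc[aged_records["age_yr"].notna()]
    if len(aged) == 0:
        raise ValueError("no aged fish: cannot build an age-length key")
    keys = aged[SURVEY_KEY].drop_duplicates()
    if len(keys) > 1:
        raise ValueError("records span multiple surveys; build one key per survey")
    species, lake_id, year = keys.iloc[0]

    lengths = aged["length_cm"].to_numpy(dtype=float)
    ages_raw = aged["age_yr"].to_numpy(dtype=float)
    lo = np.floor(lengths.min() / bin_width) * bin_width
    hi = np.ceil(lengths.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    ages = np.unique(ages_raw)
    counts = np.zeros((len(edges) - 1, len(ages)))
    b_idx = np.clip(np.searchsorted(edges, lengths, side="right") - 1, 0, len(edges) - 2)
    a_idx = np.searchsorted(ages, ages_raw)
    np.add.at(counts, (b_idx, a_idx), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals
    probs[totals[:, 0] == 0] = np.nan  # empty bins flagged
    return AgeLengthKey(str(species), str(lake_id), int(year), edges, ages, probs)


def apply_alk(
    key: AgeLengthKey,
    records: pd.DataFrame,
    seed: int,
    out_of_range: str = "drop",
) -> tuple[pd.DataFrame, int]:
    """Assign ages to every fish of the key's survey.

    Unaged fish receive a seeded draw from their bin's probability row;
    already-aged fish are unchanged.  Fish in empty or out-of-range bins
    are dropped (default) or assigned from the nearest nonempty bin
    (``out_of_range='nearest'``).  Returns the aged table and the count of
    dropped fish, so record conservation can be audited.
    """
    if out_of_range not in ("drop", "nearest"):
        raise ValueError("out_of_range must be 'drop' or 'nearest'")
    rng = np.random.default_rng(seed)
    out = records.copy()
    edges, probs = key.bin_edges, key.probs
    nonempty = np.where(np.isfinite(probs[:, 0]))[0]
    assigned_age = out["age_yr"].to_numpy(dtype=float).copy()
    drop_mask = np.zeros(len(out), dtype=bool)
    lengths = out["length_cm"].to_numpy(dtype=float)
    unaged = out["age_yr"].isna().to_numpy()
    bins = np.searchsorted(edges, lengths, side="right") - 1
    for i in np.where(unaged)[0]:
        b = bins[i]
        valid = 0 <= b < probs.shape[0] and np.isfinite(probs[b, 0])
        if not valid:
            if out_of_range == "drop":
                drop_mask[i] = True
                continue
            b = nonempty[np.argmin(np.abs(nonempty - np.clip(b, 0, probs.shape[0] - 1)))]
        assigned_age[i] = rng.choice(key.ages, p=probs[b])
    out["age_yr"] = assigned_age
    out = out.loc[~drop_mask].copy()
    out["aged_flag"] = True
    return out, int(drop_mask.sum())


def filter_surveys(
    records: pd.DataFrame,
    min_age_groups: int = 5,
    min_per_group: int = 5,
) -> pd.DataFrame:
    """Apply the 5x5 inclusion rule to every survey's aged subsample.

    A survey passes when at least ``min_age_groups`` distinct ages each
    have at least ``min_per_group`` aged fish; age groups below the quota
    do not count but do not disqualify.  Returns one row per survey with
    ``n_age_groups_meeting_quota`` and ``passed``.
    """
    aged = records.loc[records["age_yr"].notna()]
    all_surveys = records[SURVEY_KEY].drop_duplicates()
    rows = []
    grouped = dict(iter(aged.groupby(SURVEY_KEY)))
    for _, s in all_surveys.iterrows():
        grp = grouped.get((s["species"], s["lake_id"], s["year"]))
        if grp is None:
            n_ok = 0
        else:
            counts = grp["age_yr"].value_counts()
            n_ok = int((counts >= min_per_group).sum())
        rows.append(
            {
                "species": s["species"],
                "lake_id": s["lake_id"],
                "year": s["year"],
                "n_age_groups_meeting_quota": n_ok,
                "passed": n_ok >= min_age_groups,
            }
        )
    return pd.DataFrame(rows)
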