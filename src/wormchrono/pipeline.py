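"""The chronogram pipeline: filter, sort, orient, merge, render.

A COPAS run yields one longitudinal green-fluorescence profile per object,
recorded in whichever head/tail orientation the worm happened to transit
the flow cell. The pipeline reconstructs a developmental overview:

1. drop instrument artifacts (bubbles: tiny TOF with disproportionate EXT);
2. drop profiles shorter than a minimum sample count (eggs, debris, hatchling
   larvae — default 80 samples);
3. sort the remaining profiles by length (sample count), the proxy for age;
4. orient every profile head-to-tail by walking the length-sorted chain:
   each profile is kept or reversed, whichever direction correlates better
   (Pearson r on a common resampled grid) with its already-oriented
   neighbor of most similar length;
5. average all profiles of each observed exact length into one mean profile
   per length — stacking these rows, shortest at the bottom, gives the
   "chronogram", a pseudo-time heatmap of reporter expression across
   development. Lengths with no worms are skipped and recorded.

Because orientation is defined only relative to neighbors, the polarity of
the whole chronogram is arbitrary: every downstream comparison is defined
up to a global left-right mirror.

The greedy per-step choice in step 4 is globally optimal for the chain
score Σ r(neighbor_i, neighbor_i+1): each adjacency term depends only on
whether the two profiles are flipped relative to each other, so the terms
can be maximized independently (up to one global flip).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np

from .copas_io import PopulationDataset, ProfileRecord


@dataclass(frozen=True)
class ArtifactRules:
    """Event-level rejection thresholds for non-worm objects."""

    min_tof: float = 30.0
    max_ext_tof_ratio: float = 10.0


@dataclass(frozen=True)
class PipelineConfig:
    min_profile_length: int = 80
    artifact_rules: ArtifactRules = ArtifactRules()
    resample_grid: int = 100
    anchor_policy: str = "longest-first"  # or "shortest-first"

    def __post_init__(self):
        if self.min_profile_length < 2:
            raise ValueError("min_profile_length must be >= 2")
        if self.resample_grid < 2:
            raise ValueError("resample_grid must be >= 2")
        if self.anchor_policy not in ("longest-first", "shortest-first"):
            raise ValueError(f"unknown anchor_policy {self.anchor_policy!r}")


#: |r_keep - r_flip| at or below this is an orientation tie (kept as-is, flagged)
TIE_TOLERANCE = 1e-9


class Rejection(NamedTuple):
    event_id: str
    rule: str


def filter_artifact_events(
    dataset: PopulationDataset, rules: ArtifactRules = ArtifactRules()
) -> tuple[PopulationDataset, list[Rejection]]:
    """Remove events violating any artifact rule; report names the rule fired.

    Retained ∪ rejected partitions the input exactly.
    """
    rejections: list[Rejection] = []
    keep: list[str] = []
    for e in dataset.events:
        if e.tof < rules.min_tof:
            rejections.append(Rejection(e.event_id, f"TOF < {rules.min_tof}"))
        elif e.tof > 0 and e.ext / e.tof > rules.max_ext_tof_ratio:
            rejections.append(Rejection(e.event_id, f"EXT/TOF > {rules.max_ext_tof_ratio}"))
        else:
            keep.append(e.event_id)
    return dataset.subset(keep), rejections


def filter_short_profiles(
    dataset: PopulationDataset, min_profile_length: int = 80
) -> tuple[PopulationDataset, list[Rejection]]:
    """Discard small objects: keep exactly the profiles with sample count
    >= ``min_profile_length`` (removal is strictly "smaller than")."""
    if min_profile_length < 2:
        raise ValueError("min_profile_length must be >= 2")
    rejections = [
        Rejection(e.event_id, f"profile length < {min_profile_length}")
        for e in dataset.events
        if len(dataset.profiles[e.event_id]) < min_profile_length
    ]
    rejected_ids = {r.event_id for r in rejections}
    keep = [e.event_id for e in dataset.events if e.event_id not in rejected_ids]
    return dataset.subset(keep), rejections


def sort_by_length(dataset: PopulationDataset) -> list[ProfileRecord]:
    """Ascending by sample count; ties broken by event_id (stable, reproducible)."""
    return sorted(dataset.profiles.values(), key=lambda p: (len(p), p.event_id))


def resample_profile(samples: Sequence[float], m: int) -> np.ndarray:
    """Linear interpolation at ``m`` evenly spaced positions over the profile's
    index range; endpoints are preserved exactly."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if m < 2:
        raise ValueError("resampling grid must have at least 2 points")
    positions = np.linspace(0.0, samples.size - 1.0, m)
    out = np.interp(positions, np.arange(samples.size), samples)
    out[0], out[-1] = samples[0], samples[-1]
    return out


def pearson(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Pearson product-moment coefficient, or ``None`` if either sequence has
    zero variance (the correlation is then undefined)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"sequences differ in size: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        return None
    r = float(da @ db) / np.sqrt(va * vb)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class OrientedProfile:
    event_id: str
    samples: np.ndarray
    flipped: bool
    orientation_r: float | None  # None for the chain anchor
    ambiguous: bool = False  # tie or undefined r; kept as-is

    def __len__(self) -> int:
        return int(self.samples.size)


def orient_profiles(
    profiles: Sequence[ProfileRecord], config: PipelineConfig = PipelineConfig()
) -> list[OrientedProfile]:
    """Orient a length-sorted chain of profiles to one common polarity.

    The anchor (longest profile under the default policy — adults carry the
    strongest anteroposterior signature) is kept as-is; walking the chain
    toward the other end, each profile is kept or reversed, whichever
    orientation has the larger Pearson r against the previously oriented
    neighbor after both are resampled to a common grid. Ties and undefined
    correlations keep the profile as-is and set ``ambiguous``.

    Input must be sorted ascending by length; output preserves input order.
    """
    if not profiles:
        return []
    lengths = [len(p) for p in profiles]
    if lengths != sorted(lengths):
        raise ValueError("profiles must be sorted ascending by length")

    order = range(len(profiles) - 1, -1, -1) if config.anchor_policy == "longest-first" \
        else range(len(profiles))
    order = list(order)

    out: dict[int, OrientedProfile] = {}
    prev_grid: np.ndarray | None = None
    for chain_pos, idx in enumerate(order):
        p = profiles[idx]
        grid = resample_profile(p.samples, config.resample_grid)
        if chain_pos == 0:
            out[idx] = OrientedProfile(p.event_id, np.asarray(p.samples, float).copy(),
                                       flipped=False, orientation_r=None)
            prev_grid = grid
            continue
        r_keep = pearson(grid, prev_grid)
        r_flip = pearson(grid[::-1], prev_grid)
        # differences below numerical noise (e.g. palindromic profiles) are ties
        if r_keep is None or r_flip is None or abs(r_keep - r_flip) <= TIE_TOLERANCE:
            chosen_flip, winning_r, ambiguous = False, r_keep, True
        elif r_flip > r_keep:
            chosen_flip, winning_r, ambiguous = True, r_flip, False
        else:
            chosen_flip, winning_r, ambiguous = False, r_keep, False
        samples = np.asarray(p.samples, float)
        samples = samples[::-1].copy() if chosen_flip else samples.copy()
        out[idx] = OrientedProfile(p.event_id, samples, flipped=chosen_flip,
                                   orientation_r=winning_r, ambiguous=ambiguous)
        prev_grid = grid[::-1] if chosen_flip else grid
    return [out[i] for i in range(len(profiles))]


def chain_score(oriented: Sequence[OrientedProfile]) -> float:
    """Σ of the recorded winning Pearson r over the chain (anchor excluded)."""
    return float(sum(o.orientation_r for o in oriented if o.orientation_r is not None))


@dataclass
class ChronogramRow:
    length: int
    n_merged: int
    mean_profile: np.ndarray


@dataclass
class Chronogram:
    """Length-ordered stack of per-length mean profiles (ragged matrix)."""

    rows: list[ChronogramRow]
    skipped_lengths: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = [r.length for r in self.rows]
        if lengths != sorted(lengths) or len(lengths) != len(set(lengths)):
            raise ValueError("chronogram rows must be strictly increasing in length")

    @property
    def n_profiles(self) -> int:
        return sum(r.n_merged for r in self.rows)

    def lengths(self) -> list[int]:
        return [r.length for r in self.rows]

    def mirrored(self) -> "Chronogram":
        """The global left-right mirror (head/tail polarity swapped)."""
        return Chronogram(
            rows=[ChronogramRow(r.length, r.n_merged, r.mean_profile[::-1].copy())
                  for r in self.rows],
            skipped_lengths=list(self.skipped_lengths),
            provenance=dict(self.provenance),
        )


def merge_by_length(
    oriented: Sequence[OrientedProfile],
    provenance: dict | None = None,
    bin_width: int = 1,
    normalize: str = "none",
) -> Chronogram:
    """Group oriented profiles by exact sample count and average each group
    element-wise; unobserved lengths inside the observed range are recorded
    as skipped.

    Options (off by default): ``bin_width > 1`` pools lengths into
    [k·w, (k+1)·w) bins, resampling members to the longest member before
    averaging (trades length resolution for smoother rows);
    ``normalize="max"`` scales each worm to unit peak before averaging so
    rows reflect signal shape rather than absolute PMT level.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if normalize not in ("none", "max"):
        raise ValueError(f"unknown normalization {normalize!r}")
    groups: dict[int, list[np.ndarray]] = {}
    exact_lengths: set[int] = set()
    for o in oriented:
        samples = o.samples
        if normalize == "max" and samples.max() > 0:
            samples = samples / samples.max()
        groups.setdefault((len(o) // bin_width) * bin_width, []).append(samples)
        exact_lengths.add(len(o))
    rows = []
    for _, members in sorted(groups.items()):
        length = max(m.size for m in members)
        if any(m.size != length for m in members):
            members = [resample_profile(m, length) for m in members]
        rows.append(ChronogramRow(length=length, n_merged=len(members),
                                  mean_profile=np.mean(np.stack(members), axis=0)))
    if exact_lengths:
        lo, hi = min(exact_lengths), max(exact_lengths)
        observed = {r.length for r in rows} if bin_width > 1 else exact_lengths
        skipped = [L for L in range(lo, hi + 1) if L not in observed]
    else:
        skipped = []
    return Chronogram(rows=rows, skipped_lengths=skipped, provenance=dict(provenance or {}))


class PipelineResult(NamedTuple):
    chronogram: Chronogram
    oriented: list[OrientedProfile]
    rejections: list[Rejection]
    stage_counts: dict[str, int]


def build_chronogram(
    dataset: PopulationDataset, config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the full pipeline on one population and return the chronogram with
    per-stage bookkeeping (records in = records out + records rejected at
    every stage)."""
    counts = {"input": len(dataset)}
    dataset, artifact_rej = filter_artifact_events(dataset, config.artifact_rules)
    counts["after_artifact_filter"] = len(dataset)
    dataset, short_rej = filter_short_profiles(dataset, config.min_profile_length)
    counts["after_length_filter"] = len(dataset)
    ordered = sort_by_length(dataset)
    oriented = orient_profiles(ordered, config)
    chron = merge_by_length(
        oriented,
        provenance={"condition_label": dataset.condition_label, **asdict(config)},
    )
    counts["merged_rows"] = len(chron.rows)
    return PipelineResult(chron, oriented, artifact_rej + short_rej, counts)


@dataclass(frozen=True)
class RenderOptions:
    align: str = "left"        # "left" or "center"
    scaling: str = "global"    # "global" or "per-row"

    def __post_init__(self):
        if self.align not in ("left", "center"):
            raise ValueError(f"unknown align {self.align!r}")
        if self.scaling not in ("global", "per-row"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


def render_chronogram(
    chronogram: Chronogram, options: RenderOptions = RenderOptions()
) -> np.ndarray:
    """Rasterize a chronogram to a float matrix of color indices in [0, 1].

    Rows are stacked shortest at the bottom (matrix row 0 = longest worms),
    head at the left; positions outside a ragged row are NaN. Intensities
    are min-max scaled, globally by default, so the image is invariant to a
    uniform rescaling of all profiles.
    """
    if not chronogram.rows:
        raise ValueError("cannot render an empty chronogram")
    width = max(r.length for r in chronogram.rows)
    img = np.full((len(chronogram.rows), width), np.nan)
    for i, row in enumerate(reversed(chronogram.rows)):  # longest on top
        offset = (width - row.length) // 2 if options.align == "center" else 0
        values = row.mean_profile
        if options.scaling == "per-row":
            lo, hi = float(values.min()), float(values.max())
            values = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
        img[i, offset:offset + row.length] = values
    if options.scaling == "global":
        lo, hi = np.nanmin(img), np.nanmax(img)
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


def save_chronogram_png(
    chronogram: Chronogram, path, options: RenderOptions = RenderOptions(), cmap: str = "viridis"
) -> None:
    """Write the rendered chronogram as a PNG heatmap (matplotlib backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = render_chronogram(chronogram, options)
    fig, ax = plt.subplots(figsize=(6, 4), dpi=150)
    ax.imshow(img, aspect="auto", interpolation="nearest", cmap=cmap)
    ax.set_xlabel("position along body (head left)")
    ax.set_ylabel("worm length rank (short/young at bottom)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
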