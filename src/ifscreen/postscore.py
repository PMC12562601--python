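"""Two-stage post-scoring of docking-pose ensembles.

Ensemble docking produces, per receptor/ligand conformer pair ("run"),
a fixed number of top-scoring solutions; the pooled solutions then pass
through

1. a *non-specific* stage thresholding the four interface descriptors
   (BSA >= 2750 Å², MHP complementarity >= 0.5, >= 6 ionic bridges,
   >= 7 hydrogen bonds — all inclusive), and
2. a *specific* stage imposing residue-contact rules derived from
   contact-frequency heatmaps (e.g. "D170(−) must contact R32 or R34").

Run-grid bookkeeping, the filters, contact-frequency matrices and a
machine-readable funnel report live here.  The shipped rule presets are
the β2(+)/β2(−) and α4(+)/β2(−) interface rule sets of the original
screening.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .descriptors import ContactRecord, InterfaceDescriptor
from .structmodel import RegionSpec


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSiteSpec:
    """Residue ranges of one canonical binding-site face."""

    role: str            # '+' or '-'
    subunit: str         # e.g. 'b2', 'a4', 'generic'
    ranges: RegionSpec

    def __post_init__(self):
        if not self.ranges.segments:
            raise ValueError("binding site needs at least one residue range")


#: canonical binding-site residue ranges allowed for docking (author numbering)
BINDING_SITES: dict[str, tuple[tuple[int, int], ...]] = {
    "b2+": ((21, 35), (46, 50), (60, 64), (94, 103), (110, 120), (129, 167),
            (177, 206), (261, 271), (455, 477)),
    "b2-": ((31, 45), (52, 63), (76, 83), (106, 125), (136, 142), (158, 184),
            (204, 210), (455, 477)),
    "a4+": ((24, 38), (49, 53), (62, 67), (97, 105), (113, 123), (132, 172),
            (182, 214), (267, 277)),
    "a4-": ((33, 49), (54, 66), (77, 87), (109, 128), (139, 146), (161, 187),
            (210, 216)),
}


@dataclass(frozen=True)
class NonSpecificCriteria:
    """Inclusive descriptor thresholds of the first filtering stage."""

    bsa_min: float = 2750.0
    mhp_min: float = 0.5
    ionic_min: int = 6
    hbond_min: int = 7

    def __post_init__(self):
        if min(self.bsa_min, self.mhp_min, self.ionic_min, self.hbond_min) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class SpecificContactRule:
    """'At least one pair in contact' between two residue groups.

    ``receptor_residues`` is a set of (seq_id, role) with role '+' or '-';
    ``ligand_residues`` a set of ligand seq_ids.  A pose satisfies the
    rule when any contact of a qualifying kind joins any residue of the
    left set to any residue of the right set.
    """

    receptor_residues: frozenset    # of (seq_id, role)
    ligand_residues: frozenset      # of seq_id
    label: str = ""

    def __post_init__(self):
        if not self.receptor_residues or not self.ligand_residues:
            raise ValueError("rule groups must be non-empty")

    def satisfied_by(self, contacts: list[ContactRecord],
                     kinds: frozenset = frozenset({"H", "I"})) -> bool:
        for c in contacts:
            if not (c.kinds & kinds):
                continue
            if (c.receptor_residue[1], c.receptor_role) in self.receptor_residues \
                    and c.ligand_residue[1] in self.ligand_residues:
                return True
        return False


def _rule(rec, lig, label):
    return SpecificContactRule(frozenset(rec), frozenset(lig), label)


def criteria_from_yaml(path) -> NonSpecificCriteria:
    """Load thresholds from YAML (keys bsa_min, mhp_min, ionic_min, hbond_min)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return NonSpecificCriteria(**data)


def rules_from_yaml(path) -> tuple[SpecificContactRule, ...]:
    """Load contact rules from YAML.

    Format::

        rules:
          - label: "D170(-) -> R32,R34"
            receptor: [[170, "-"]]
            ligand: [32, 34]
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    rules = []
    for item in data["rules"]:
        rules.append(SpecificContactRule(
            frozenset((int(s), r) for s, r in item["receptor"]),
            frozenset(int(s) for s in item["ligand"]),
            item.get("label", "")))
    return tuple(rules)


def rules_to_yaml(rules, path) -> None:
    import yaml

    payload = {"rules": [
        {"label": r.label,
         "receptor": sorted([s, role] for s, role in r.receptor_residues),
         "ligand": sorted(r.ligand_residues)}
        for r in rules]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


#: imposed-interaction rule sets of the original screening
RULES_B2_B2: tuple[SpecificContactRule, ...] = (
    _rule({(147, "+"), (186, "+")}, {13, 14, 52, 53, 68}, "K147(+)/R186(+) -> E13,D14,D52,D53,D68"),
    _rule({(192, "+"), (193, "+")}, {32, 34}, "D192(+)/D193(+) -> R32,R34"),
    _rule({(170, "-")}, {32, 34}, "D170(-) -> R32,R34"),
    _rule({(171, "-")}, {32, 34}, "D171(-) -> R32,R34"),
)

RULES_A4_B2: tuple[SpecificContactRule, ...] = (
    _rule({(193, "+"), (194, "+")}, {13, 14, 52, 53, 68}, "R193(+)/K194(+) -> E13,D14,D52,D53,D68"),
    _rule({(170, "-")}, {32, 34}, "D170(-) -> R32,R34"),
    _rule({(171, "-"), (196, "+")}, {32, 34}, "D171(-)/E196(+) -> R32,R34"),
)


# ---------------------------------------------------------------------------
# Pose bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    pose_id: int
    ligand_conformer: int
    receptor_conformer: int
    engine_score: float = 0.0


@dataclass
class PoseEnsemble:
    poses: list[Pose]
    interface_label: str = "custom"

    def __len__(self):
        return len(self.poses)


@dataclass
class RunPlan:
    n_runs: int
    n_retained: int
    grid: list[tuple[int, int]]


def plan_runs(n_ligand_conformers: int, n_receptor_conformers: int,
              top_k: int) -> RunPlan:
    """Docking run grid: one run per conformer pair, top_k kept per run."""
    if min(n_ligand_conformers, n_receptor_conformers, top_k) < 1:
        raise ValueError("conformer counts and top_k must be >= 1")
    n_runs = n_ligand_conformers * n_receptor_conformers
    grid = [(i, j) for i in range(n_ligand_conformers)
            for j in range(n_receptor_conformers)]
    return RunPlan(n_runs, n_runs * top_k, grid)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass
class FilterStage:
    name: str
    n_input: int
    n_surviving: int
    rejections: dict[str, int] = field(default_factory=dict)
    survivors: list[int] = field(default_factory=list)
    kills: dict[int, list[str]] = field(default_factory=dict)


def nonspecific_filter(descriptors: list[InterfaceDescriptor],
                       criteria: NonSpecificCriteria | None = None
                       ) -> tuple[list[int], FilterStage]:
    """Keep poses whose four descriptors all meet the (inclusive) thresholds.

    A pose with an undefined MHP score (no buried surface) is rejected and
    tallied under ``mhp_undefined``.  A pose may contribute to several
    rejection tallies.
    """
    criteria = criteria or NonSpecificCriteria()
    tallies = {"bsa": 0, "mhp": 0, "ionic": 0, "hbond": 0, "mhp_undefined": 0}
    survivors: list[int] = []
    kills: dict[int, list[str]] = {}
    for i, d in enumerate(descriptors):
        failed = []
        if d.bsa < criteria.bsa_min:
            failed.append("bsa")
        if d.mhp_score is None:
            failed.append("mhp_undefined")
        elif d.mhp_score < criteria.mhp_min:
            failed.append("mhp")
        if d.n_ionic < criteria.ionic_min:
            failed.append("ionic")
        if d.n_hbonds < criteria.hbond_min:
            failed.append("hbond")
        if failed:
            for f in failed:
                tallies[f] += 1
            kills[i] = failed
        else:
            survivors.append(i)
    stage = FilterStage("nonspecific", len(descriptors), len(survivors),
                        tallies, survivors, kills)
    return survivors, stage


def specific_filter(contacts_per_pose: list[list[ContactRecord]],
                    rules: tuple[SpecificContactRule, ...],
                    mode: str = "all_rules",
                    kinds: frozenset = frozenset({"H", "I"}),
                    pose_ids: list[int] | None = None
                    ) -> tuple[list[int], FilterStage]:
    """Impose contact rules on poses; default requires every rule at once.

    ``mode='any_rule'`` keeps a pose satisfying at least one rule.  The
    stage report lists, for each rejected pose, the rules it failed.
    """
    if mode not in ("all_rules", "any_rule"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = pose_ids if pose_ids is not None else list(range(len(contacts_per_pose)))
    survivors: list[int] = []
    kills: dict[int, list[str]] = {}
    tallies = {r.label or f"rule{ri}": 0 for ri, r in enumerate(rules)}
    for pid, contacts in zip(ids, contacts_per_pose):
        sat = [r.satisfied_by(contacts, kinds) for r in rules]
        ok = all(sat) if mode == "all_rules" else any(sat)
        if ok:
            survivors.append(pid)
        else:
            failed = [r.label or f"rule{ri}"
                      for ri, (r, s) in enumerate(zip(rules, sat)) if not s]
            for f in failed:
                tallies[f] += 1
            kills[pid] = failed
    stage = FilterStage("specific", len(contacts_per_pose), len(survivors),
                        tallies, survivors, kills)
    return survivors, stage


# ---------------------------------------------------------------------------
# Contact frequencies
# ---------------------------------------------------------------------------

@dataclass
class ContactFrequencies:
    """Residue-pair contact frequencies over a pose ensemble.

    ``overall`` is a ligand-residue x receptor-residue DataFrame of
    fractions in [0, 1]; ``by_kind`` holds one such matrix per
    interaction kind; ``counts`` the integer numerators; ``n_poses`` the
    shared denominator.  Entries are exact rationals k / n_poses.
    """

    overall: pd.DataFrame
    by_kind: dict[str, pd.DataFrame]
    counts: pd.DataFrame
    n_poses: int

    def to_tsv(self, path) -> None:
        self.overall.to_csv(path, sep="\t")

    def plot(self, kind: str | None = None, ax=None):
        """Contact-frequency heatmap (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        mat = self.overall if kind is None else self.by_kind[kind]
        if ax is None:
            _, ax = plt.subplots(
                figsize=(1 + 0.4 * mat.shape[1], 1 + 0.4 * mat.shape[0]))
        im = ax.imshow(mat.to_numpy(dtype=float), vmin=0, vmax=1,
                       cmap="viridis", aspect="auto")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90)
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_xlabel("receptor residue")
        ax.set_ylabel("ligand residue")
        ax.figure.colorbar(im, ax=ax, label="contact frequency")
        return ax


def contact_frequency(contacts_per_pose: list[list[ContactRecord]]
                      ) -> ContactFrequencies:
    """Fraction of poses in which each (ligand, receptor) pair is in contact."""
    n = len(contacts_per_pose)
    if n == 0:
        raise ValueError("empty pose ensemble")
    counts: dict[tuple[str, str], int] = {}
    kind_counts: dict[str, dict[tuple[str, str], int]] = {
        "H": {}, "I": {}, "S": {}}
    for contacts in contacts_per_pose:
        seen = set()
        seen_kind = {"H": set(), "I": set(), "S": set()}
        for c in contacts:
            key = (c.ligand_label, c.receptor_label)
            if key not in seen:
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
            for k in c.kinds:
                if key not in seen_kind[k]:
                    seen_kind[k].add(key)
                    kind_counts[k][key] = kind_counts[k].get(key, 0) + 1

    def to_frame(d: dict[tuple[str, str], int]) -> pd.DataFrame:
        if not d:
            return pd.DataFrame()
        rows = sorted({k[0] for k in d})
        cols = sorted({k[1] for k in d})
        mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
        for (lr, rr), v in d.items():
            mat.loc[lr, rr] = v
        return mat

    cnt = to_frame(counts)
    overall = cnt / n if not cnt.empty else cnt.astype(float)
    by_kind = {k: (to_frame(v) / n if v else pd.DataFrame())
               for k, v in kind_counts.items()}
    return ContactFrequencies(overall, by_kind, cnt, n)


# ---------------------------------------------------------------------------
# Funnel report
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    interface_label: str
    n_input: int
    stages: list[FilterStage]
    final_pose_ids: list[int]

    @property
    def n_final(self) -> int:
        return len(self.final_pose_ids)

    def to_dict(self) -> dict:
        return {
            "interface_label": self.interface_label,
            "n_input": self.n_input,
            "stages": [
                {"name": s.name, "n_input": s.n_input,
                 "n_surviving": s.n_surviving, "rejections": s.rejections,
                 "survivors": s.survivors,
                 "kills": {str(k): v for k, v in s.kills.items()}}
                for s in self.stages
            ],
            "final_pose_ids": self.final_pose_ids,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FilterReport":
        stages = [FilterStage(s["name"], s["n_input"], s["n_surviving"],
                              s["rejections"], s["survivors"],
                              {int(k): v for k, v in s["kills"].items()})
                  for s in d["stages"]]
        return cls(d["interface_label"], d["n_input"], stages,
                   d["final_pose_ids"])

    @classmethod
    def from_json(cls, text: str) -> "FilterReport":
        return cls.from_dict(json.loads(text))

    def summary(self) -> str:
        lines = [f"Interface {self.interface_label}: {self.n_input} poses in"]
        for s in self.stages:
            lines.append(
                f"  after {s.name:<12} {s.n_surviving:>8} "
                f"(rejected {s.n_input - s.n_surviving})"
            )
        lines.append(f"  final: {self.n_final} poses")
        return "\n".join(lines)


def funnel_report(interface_label: str, stages: list[FilterStage]
                  ) -> FilterReport:
    """Assemble the per-stage funnel; stage counts must chain consistently."""
    if not stages:
        raise ValueError("need at least one stage")
    for a, b in zip(stages, stages[1:]):
        if b.n_input != a.n_surviving:
            raise ValueError(
                f"stage {b.name!r} input {b.n_input} != previous survivors "
                f"{a.n_surviving}"
            )
    return FilterReport(interface_label, stages[0].n_input, stages,
                        list(stages[-1].survivors))


def composite_rank(descriptors: list[InterfaceDescriptor],
                   pose_ids: list[int] | None = None) -> list[int]:
    """Deterministic stand-in for the final by-eye pose choice.

    Ranks poses by the sum of z-scores of the four descriptors (undefined
    MHP treated as the ensemble minimum); highest first.
    """
    ids = pose_ids if pose_ids is not None else list(range(len(descriptors)))
    cols = []
    mhp_vals = [d.mhp_score for d in descriptors if d.mhp_score is not None]
    mhp_floor = min(mhp_vals) if mhp_vals else 0.0
    for d in descriptors:
        cols.append([d.bsa, d.mhp_score if d.mhp_score is not None else mhp_floor,
                     d.n_ionic, d.n_hbonds])
    arr = np.asarray(cols, dtype=float)
    std = arr.std(axis=0)
    std[std == 0] = 1.0
    z = (arr - arr.mean(axis=0)) / std
    order = np.argsort(-z.sum(axis=1), kind="stable")
    return [ids[i] for i in order]
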