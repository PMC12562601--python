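"""Contact-lifetime analysis of trajectory frames.

Mirrors the MD contact-persistence methodology used to tabulate key
binding residues: per-frame typed contacts, discard of an equilibration
window (default first 30 ns), lifetime fractions as exact rationals over
retained frames, a >= 20% reporting class and a >= 50% highlight class
(both inclusive), optional per-segment reporting (e.g. before/after a
ligand rearrangement), and a step heuristic over the RMSD time series to
flag candidate rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .descriptors import ContactRecord, InteractionGeometry, enumerate_contacts
from .structmodel import RegionSpec, StructureModel, select, superpose


def _as_fraction(x) -> Fraction:
    """Convert user thresholds exactly (0.2 the decimal, not the float)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass
class PersistenceConfig:
    equilibration_ns: float = 30.0
    report_min: object = Fraction(20, 100)     # inclusive lower bound to report
    highlight_min: object = Fraction(50, 100)  # inclusive bound for highlighting
    window_split: list[tuple[float, float]] | None = None  # (start, end) ns

    def __post_init__(self):
        self.report_min = _as_fraction(self.report_min)
        self.highlight_min = _as_fraction(self.highlight_min)
        if not (0 <= self.report_min <= self.highlight_min <= 1):
            raise ValueError("need 0 <= report_min <= highlight_min <= 1")


def frame_contacts(frames: StructureModel, partition: dict[str, str],
                   ligand_chains: set[str],
                   geometry: InteractionGeometry | None = None,
                   glycan_parents: dict | None = None
                   ) -> list[list[ContactRecord]]:
    """Typed contacts per trajectory frame.

    ``frames`` must carry frame_times; ``ligand_chains`` names the chains
    of the ligand partner, every other chain is receptor and must appear
    in ``partition``.
    """
    if frames.frame_times is None:
        raise ValueError("frames must carry frame_times")
    geometry = geometry or InteractionGeometry()
    lig_res = [r for r in frames.residues if r.chain_id in ligand_chains]
    rec_res = [r for r in frames.residues if r.chain_id not in ligand_chains]
    if not lig_res or not rec_res:
        raise ValueError("ligand/receptor chain split is empty on one side")

    def _sub(residues):
        from dataclasses import replace

        idx, new_res, pos = [], [], 0
        for r in residues:
            n = r.stop - r.start
            idx.extend(range(r.start, r.stop))
            new_res.append(replace(r, start=pos, stop=pos + n))
            pos += n
        return idx, new_res

    lidx, lres = _sub(lig_res)
    ridx, rres = _sub(rec_res)
    out = []
    for mi in range(frames.n_models):
        lig = StructureModel([frames.atoms[i] for i in lidx], lres,
                             frames.coords[mi, lidx])
        rec = StructureModel([frames.atoms[i] for i in ridx], rres,
                             frames.coords[mi, ridx])
        out.append(enumerate_contacts(rec, lig, geometry, partition,
                                      glycan_parents))
    return out


@dataclass
class LifetimeTable:
    """Per (residue pair, kind, segment) lifetime fractions.

    ``table`` columns: ligand_res, receptor_res, role, kind, glycan,
    fraction (exact Fraction), fraction_float, n_frames, n_present,
    highlighted, segment.
    """

    table: pd.DataFrame
    config: PersistenceConfig

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["fraction"] = df["fraction"].astype(float)
        df.to_csv(path, sep="\t", index=False)


def lifetimes(contacts_per_frame: list[list[ContactRecord]],
              times_ns: np.ndarray,
              config: PersistenceConfig | None = None) -> LifetimeTable:
    """Aggregate per-frame contacts into lifetime fractions.

    Frames with t < equilibration_ns are discarded; the fraction for a
    (pair, kind) is present-frames / retained-frames, exactly.  Rows below
    report_min are dropped; rows at or above highlight_min are flagged.
    With ``window_split``, fractions are computed per segment (inclusive
    bounds) and labelled.
    """
    config = config or PersistenceConfig()
    times = np.asarray(times_ns, dtype=float)
    if len(times) != len(contacts_per_frame):
        raise ValueError("times and contact lists differ in length")
    keep = times >= config.equilibration_ns
    if not keep.any():
        raise ValueError("all frames fall inside the equilibration window")

    if config.window_split:
        segments = [(f"{lo:g}-{hi:g}ns", (times >= lo) & (times <= hi) & keep)
                    for lo, hi in config.window_split]
    else:
        segments = [("all", keep)]

    rows = []
    for label, mask in segments:
        idx = np.nonzero(mask)[0]
        n = len(idx)
        if n == 0:
            continue
        present: dict[tuple, int] = {}
        meta: dict[tuple, ContactRecord] = {}
        for fi in idx:
            seen = set()
            for c in contacts_per_frame[fi]:
                for kind in c.kinds:
                    key = (c.ligand_residue, c.receptor_residue, kind)
                    if key in seen:
                        continue
                    seen.add(key)
                    present[key] = present.get(key, 0) + 1
                    meta.setdefault(key, c)
        for key, k in present.items():
            frac = Fraction(k, n)
            if frac < config.report_min:
                continue
            c = meta[key]
            rows.append({
                "ligand_res": c.ligand_label,
                "receptor_res": c.receptor_label,
                "role": c.receptor_role,
                "kind": key[2],
                "glycan": c.partner_is_glycan,
                "fraction": frac,
                "fraction_float": float(frac),
                "n_frames": n,
                "n_present": k,
                "highlighted": frac >= config.highlight_min,
                "segment": label,
            })
    df = pd.DataFrame(rows, columns=[
        "ligand_res", "receptor_res", "role", "kind", "glycan", "fraction",
        "fraction_float", "n_frames", "n_present", "highlighted", "segment"])
    if len(df):
        df = df.sort_values(
            ["segment", "ligand_res", "receptor_res", "kind"]
        ).reset_index(drop=True)
    return LifetimeTable(df, config)


@dataclass
class RmsdSeries:
    times_ns: np.ndarray
    rmsd: np.ndarray
    changepoints: list[int]     # indices into the retained-frame series
    flags: np.ndarray           # boolean per retained frame


def rmsd_timeseries(frames: StructureModel, region: RegionSpec | None = None,
                    reference: str | np.ndarray = "first_retained",
                    atom_filter: str = "backbone",
                    equilibration_ns: float = 0.0,
                    jump_threshold: float = 1.5,
                    sustain_frames: int = 5) -> RmsdSeries:
    """Superposed RMSD vs a reference over time, with a step detector.

    The detector flags the first frame i where the RMSD exceeds the
    running pre-step baseline (median of frames before i) by
    ``jump_threshold`` Å for at least ``sustain_frames`` consecutive
    frames; such sustained jumps are candidate rearrangements.
    """
    if frames.frame_times is None:
        raise ValueError("frames must carry frame_times")
    sub = select(frames, region, atom_filter)
    keep = frames.frame_times >= equilibration_ns
    coords = sub.coords[keep]
    times = frames.frame_times[keep]
    if len(coords) < 2:
        raise ValueError("need at least 2 retained frames")
    if isinstance(reference, str):
        if reference != "first_retained":
            raise ValueError(f"unknown reference {reference!r}")
        ref = coords[0]
    else:
        ref = np.asarray(reference, dtype=float)
    series = np.array([superpose(c, ref)[2] for c in coords])

    flags = np.zeros(len(series), dtype=bool)
    changepoints: list[int] = []
    for i in range(1, len(series)):
        baseline = float(np.median(series[:i]))
        if series[i] <= baseline + jump_threshold:
            continue
        # rising edge only: the previous frame was still at baseline level
        prev_base = float(np.median(series[: max(i - 1, 1)]))
        if i > 1 and series[i - 1] > prev_base + jump_threshold:
            continue
        window = series[i : i + sustain_frames]
        if len(window) == sustain_frames and \
                np.all(window > baseline + jump_threshold):
            changepoints.append(i)
            flags |= np.arange(len(series)) >= i
    return RmsdSeries(times, series, changepoints, flags)
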