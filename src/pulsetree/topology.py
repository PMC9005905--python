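"""Arterial tree data model, file I/O, surgery and path measurement.

The tree is a rooted, acyclic branching network of tapered 1-D vessel
segments.  Terminal segments carry a three-element Windkessel outlet
representing the distal vascular bed.  Kidney configurations (2KDN, 1KDN,
0KDN, TX) are produced by surgery operations on a two-kidney reference
tree: removal of terminal renal segments and, for the transplant case,
re-attachment of a renal branch onto the external iliac artery.

All quantities in this module are in file units: lengths cm, diameters mm,
distensibility kPa^-1 x 10^-3, Windkessel R in mmHg.s/mL and C in mL/mmHg.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable


class TopologyError(ValueError):
    """Structural or schema violation in an arterial tree."""


@dataclass
class WindkesselOutlet:
    """Three-element terminal load (RCR).

    R1 is the proximal (characteristic) resistance, R2 the distal
    resistance, C the compliance, P_out the distal outflow pressure.
    Units: mmHg.s/mL, mL/mmHg, mmHg.
    """

    R1: float
    R2: float
    C: float
    P_out: float = 5.0

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0 or self.C <= 0:
            raise TopologyError(
                f"Windkessel parameters must be positive, got "
                f"R1={self.R1}, R2={self.R2}, C={self.C}"
            )

    @property
    def total_resistance(self) -> float:
        return self.R1 + self.R2


@dataclass
class Segment:
    """One tapered 1-D vessel segment.

    ``distensibility_ref`` is the wall distensibility (1/A dA/dP) at the
    reference pressure, in kPa^-1 x 10^-3; ``group`` names the arterial
    territory the segment belongs to (aorta, carotid, brachial, ...) and
    is what the in-vivo override table keys on.
    """

    id: int
    name: str
    length: float                  # cm
    diameter_prox: float           # mm
    diameter_dist: float           # mm
    distensibility_ref: float      # kPa^-1 x 10^-3
    parent_id: int | None = None
    child_ids: list[int] = field(default_factory=list)
    windkessel: WindkesselOutlet | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TopologyError(f"segment {self.id}: length must be > 0")
        if self.diameter_prox <= 0 or self.diameter_dist <= 0:
            raise TopologyError(f"segment {self.id}: diameters must be > 0")
        if self.diameter_dist > self.diameter_prox + 1e-12:
            raise TopologyError(
                f"segment {self.id}: distal diameter exceeds proximal "
                f"(segments taper)"
            )
        if self.distensibility_ref <= 0:
            raise TopologyError(f"segment {self.id}: distensibility must be > 0")

    @property
    def terminal(self) -> bool:
        return not self.child_ids

    @property
    def mean_diameter(self) -> float:
        return 0.5 * (self.diameter_prox + self.diameter_dist)


@dataclass
class PathMeasurement:
    """Tree path between two named measurement sites.

    ``distance`` (cm) is the sum of the traversed segment lengths, with
    partial lengths at the two end segments measured from the site
    positions; this mirrors how inter-site distance is obtained by adding
    up the lengths of the segments along the anatomical path.
    """

    site_a: str
    site_b: str
    segment_chain: list[int]
    distance: float

    @property
    def distance_m(self) -> float:
        return self.distance * 1e-2


@dataclass
class KidneyConfiguration:
    """Descriptor of a staged-kidney-removal scenario.

    2KDN: control, both renal arteries in place.
    1KDN: left renal artery removed.
    0KDN: both renal arteries removed.
    TX:   both removed, right renal branch re-attached onto the external
          iliac artery (donor segment grafted onto the target segment).
    """

    name: str
    removed_segment_ids: list[int] = field(default_factory=list)
    transplant: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.name == "2KDN" and (self.removed_segment_ids or self.transplant):
            raise TopologyError("2KDN is the unmodified control")
        if self.name == "TX" and self.transplant is None:
            raise TopologyError("TX requires a (donor, target) transplant pair")


#: Segment ids of the named renal/iliac segments in the reference tree.
LEFT_RENAL_ID = 36
RIGHT_RENAL_ID = 38
EXTERNAL_ILIAC_ID = 44

STANDARD_CONFIGURATIONS = {
    "2KDN": KidneyConfiguration("2KDN"),
    "1KDN": KidneyConfiguration("1KDN", removed_segment_ids=[LEFT_RENAL_ID]),
    "0KDN": KidneyConfiguration(
        "0KDN", removed_segment_ids=[LEFT_RENAL_ID, RIGHT_RENAL_ID]
    ),
    "TX": KidneyConfiguration(
        "TX",
        removed_segment_ids=[LEFT_RENAL_ID, RIGHT_RENAL_ID],
        transplant=(RIGHT_RENAL_ID, EXTERNAL_ILIAC_ID),
    ),
}


class ArterialTree:
    """Rooted tree of :class:`Segment` objects with named measurement sites.

    ``named_sites`` maps a site name (carotid, femoral, radial, ...) to a
    ``(segment_id, position_cm)`` pair, the position measured from the
    proximal end of the segment.
    """

    def __init__(
        self,
        segments: Iterable[Segment],
        root_id: int,
        named_sites: dict[str, tuple[int, float]] | None = None,
        meta: dict | None = None,
    ) -> None:
        self.segments: dict[int, Segment] = {s.id: s for s in segments}
        self.root_id = root_id
        self.named_sites = dict(named_sites or {})
        self.meta = dict(meta or {})
        self.validate()

    # ------------------------------------------------------------------ #
    # structure

    def __contains__(self, seg_id: int) -> bool:
        return seg_id in self.segments

    def __getitem__(self, seg_id: int) -> Segment:
        return self.segments[seg_id]

    @property
    def terminal_ids(self) -> list[int]:
        return [s.id for s in self.segments.values() if s.terminal]

    def copy(self) -> "ArterialTree":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check connectivity, acyclicity and terminal/Windkessel pairing."""
        if self.root_id not in self.segments:
            raise TopologyError(f"root id {self.root_id} not among segments")
        if self.segments[self.root_id].parent_id is not None:
            raise TopologyError("root segment must have no parent")
        for seg in self.segments.values():
            for cid in seg.child_ids:
                if cid not in self.segments:
                    raise TopologyError(
                        f"segment {seg.id} references missing child {cid}"
                    )
                if self.segments[cid].parent_id != seg.id:
                    raise TopologyError(
                        f"child {cid} does not point back to parent {seg.id}"
                    )
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise TopologyError(
                        f"segment {seg.id} references missing parent "
                        f"{seg.parent_id}"
                    )
                if seg.id not in self.segments[seg.parent_id].child_ids:
                    raise TopologyError(
                        f"parent {seg.parent_id} does not list child {seg.id}"
                    )
            if seg.terminal and seg.windkessel is None:
                raise TopologyError(
                    f"terminal segment {seg.id} has no Windkessel outlet"
                )
            if not seg.terminal and seg.windkessel is not None:
                raise TopologyError(
                    f"non-terminal segment {seg.id} carries a Windkessel"
                )
        # reachability + acyclicity from the root
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise TopologyError(f"cycle detected at segment {sid}")
            seen.add(sid)
            stack.extend(self.segments[sid].child_ids)
        if seen != set(self.segments):
            orphans = sorted(set(self.segments) - seen)
            raise TopologyError(f"segments not reachable from root: {orphans}")
        for name, (sid, pos) in self.named_sites.items():
            if sid not in self.segments:
                raise TopologyError(f"site {name!r} on missing segment {sid}")
            if not 0.0 <= pos <= self.segments[sid].length + 1e-9:
                raise TopologyError(
                    f"site {name!r} position {pos} cm outside segment {sid}"
                )

    # ------------------------------------------------------------------ #
    # paths

    def _chain_to_root(self, seg_id: int) -> list[int]:
        chain = [seg_id]
        while self.segments[chain[-1]].parent_id is not None:
            chain.append(self.segments[chain[-1]].parent_id)
        return chain

    def site_location(self, site: str) -> tuple[int, float]:
        if site not in self.named_sites:
            raise TopologyError(
                f"unknown site {site!r}; known sites: "
                f"{sorted(self.named_sites)}"
            )
        return self.named_sites[site]

    def arterial_path(self, site_a: str, site_b: str) -> PathMeasurement:
        """Distance between two sites along the tree (via the nearest
        common ancestor), by summing traversed segment lengths."""
        sid_a, pos_a = self.site_location(site_a)
        sid_b, pos_b = self.site_location(site_b)
        up_a = self._chain_to_root(sid_a)
        up_b = self._chain_to_root(sid_b)
        set_b = set(up_b)
        nca = next(s for s in up_a if s in set_b)
        leg_a = up_a[: up_a.index(nca) + 1]       # sid_a ... nca
        leg_b = up_b[: up_b.index(nca) + 1]       # sid_b ... nca

        if sid_a == sid_b:
            dist = abs(pos_a - pos_b)
            chain = [sid_a]
        elif nca == sid_a:
            # a is an ancestor of b: distance from pos_a down to pos_b
            dist = (self.segments[sid_a].length - pos_a) + pos_b
            for sid in leg_b[1:-1]:
                dist += self.segments[sid].length
            chain = list(reversed(leg_b))
        elif nca == sid_b:
            dist = (self.segments[sid_b].length - pos_b) + pos_a
            for sid in leg_a[1:-1]:
                dist += self.segments[sid].length
            chain = leg_a
        else:
            # up from a to just below the NCA, then down to b
            dist = pos_a + pos_b
            for sid in leg_a[1:-1]:
                dist += self.segments[sid].length
            for sid in leg_b[1:-1]:
                dist += self.segments[sid].length
            chain = leg_a[:-1] + list(reversed(leg_b[:-1]))
        return PathMeasurement(site_a, site_b, chain, dist)

    # ------------------------------------------------------------------ #
    # surgery

    def remove_segment(self, segment_id: int) -> "ArterialTree":
        """Remove a terminal segment (and its Windkessel) from a copy of
        the tree.  Removing a non-terminal segment would orphan its
        subtree and is refused."""
        if segment_id not in self.segments:
            raise TopologyError(f"segment {segment_id} not in tree")
        seg = self.segments[segment_id]
        if not seg.terminal:
            raise TopologyError(
                f"segment {segment_id} is not terminal; removing it would "
                f"orphan its subtree"
            )
        if seg.parent_id is None:
            raise TopologyError("cannot remove the root segment")
        new = self.copy()
        parent = new.segments[seg.parent_id]
        parent.child_ids = [c for c in parent.child_ids if c != segment_id]
        del new.segments[segment_id]
        new.named_sites = {
            k: v for k, v in new.named_sites.items() if v[0] != segment_id
        }
        if parent.terminal:
            raise TopologyError(
                f"removing segment {segment_id} left parent {parent.id} "
                f"without children or a Windkessel"
            )
        new.validate()
        return new

    def transplant_segment(
        self, donor_id: int, target_id: int, donor_tree: "ArterialTree"
    ) -> "ArterialTree":
        """Graft a copy of ``donor_id`` (taken from ``donor_tree``, the
        original two-kidney reference) onto terminal segment ``target_id``.

        The target's Windkessel is removed and the target becomes a
        junction feeding (a) a new branch bearing the donor segment's
        geometry, wall and Windkessel properties and (b) a distal
        continuation segment that inherits the target's distal geometry
        and original Windkessel, so downstream outflow is preserved.
        """
        if donor_id not in donor_tree.segments:
            raise TopologyError(
                f"donor segment {donor_id} unknown in the original tree"
            )
        if target_id not in self.segments:
            raise TopologyError(f"target segment {target_id} not in tree")
        target = self.segments[target_id]
        if not target.terminal or target.windkessel is None:
            raise TopologyError(
                f"transplant target {target_id} must be a terminal segment "
                f"with a Windkessel outlet"
            )
        donor = donor_tree.segments[donor_id]
        if donor.windkessel is None:
            raise TopologyError(
                f"donor segment {donor_id} carries no Windkessel; its "
                f"vascular properties are incomplete"
            )
        new = self.copy()
        tgt = new.segments[target_id]
        graft_id = max(new.segments) + 1
        cont_id = graft_id + 1
        graft = Segment(
            id=graft_id,
            name=f"{donor.name}_graft",
            length=donor.length,
            diameter_prox=donor.diameter_prox,
            diameter_dist=donor.diameter_dist,
            distensibility_ref=donor.distensibility_ref,
            parent_id=target_id,
            windkessel=copy.deepcopy(donor.windkessel),
            group=donor.group,
        )
        continuation = Segment(
            id=cont_id,
            name=f"{tgt.name}_distal",
            length=2.0,
            diameter_prox=tgt.diameter_dist,
            diameter_dist=tgt.diameter_dist,
            distensibility_ref=tgt.distensibility_ref,
            parent_id=target_id,
            windkessel=tgt.windkessel,
            group=tgt.group,
        )
        tgt.windkessel = None
        tgt.child_ids = [graft_id, cont_id]
        new.segments[graft_id] = graft
        new.segments[cont_id] = continuation
        new.validate()
        return new

    def apply_kidney_configuration(
        self, config: KidneyConfiguration | str
    ) -> "ArterialTree":
        """Build a kidney configuration from the two-kidney reference.

        2KDN returns an unmodified copy; 1KDN/0KDN remove renal
        terminals; TX removes both and grafts the right renal branch
        onto the external iliac artery.
        """
        if isinstance(config, str):
            if config not in STANDARD_CONFIGURATIONS:
                raise TopologyError(
                    f"unknown configuration {config!r}; expected one of "
                    f"{sorted(STANDARD_CONFIGURATIONS)}"
                )
            config = STANDARD_CONFIGURATIONS[config]
        tree = self.copy()
        for sid in config.removed_segment_ids:
            tree = tree.remove_segment(sid)
        if config.transplant is not None:
            donor_id, target_id = config.transplant
            tree = tree.transplant_segment(donor_id, target_id, self)
        return tree


# ---------------------------------------------------------------------- #
# file I/O

SCHEMA_UNITS = {
    "length": "cm",
    "diameter": "mm",
    "distensibility": "kPa^-1 x 1e-3",
    "resistance": "mmHg.s/mL",
    "compliance": "mL/mmHg",
    "pressure": "mmHg",
}


def tree_to_dict(tree: ArterialTree) -> dict:
    segs = []
    for seg in sorted(tree.segments.values(), key=lambda s: s.id):
        d = asdict(seg)
        if seg.windkessel is None:
            d.pop("windkessel")
        segs.append(d)
    return {
        "format": "pulsetree-topology",
        "units": SCHEMA_UNITS,
        "root_id": tree.root_id,
        "named_sites": {
            k: [int(v[0]), float(v[1])] for k, v in tree.named_sites.items()
        },
        "meta": tree.meta,
        "segments": segs,
    }


def tree_from_dict(data: dict) -> ArterialTree:
    for key in ("root_id", "segments"):
        if key not in data:
            raise TopologyError(f"topology file missing required field {key!r}")
    segments = []
    for raw in data["segments"]:
        raw = dict(raw)
        try:
            wk = raw.pop("windkessel", None)
            if wk is not None:
                wk = WindkesselOutlet(**wk)
            raw.pop("terminal", None)   # derived, tolerated on input
            segments.append(Segment(windkessel=wk, **raw))
        except TypeError as exc:
            raise TopologyError(f"bad segment record: {exc}") from exc
    sites = {
        k: (int(v[0]), float(v[1]))
        for k, v in data.get("named_sites", {}).items()
    }
    return ArterialTree(
        segments, data["root_id"], named_sites=sites, meta=data.get("meta")
    )


def load_tree(path: str | Path) -> ArterialTree:
    """Load and validate an arterial tree from a JSON topology file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TopologyError(f"{path}: not valid JSON ({exc})") from exc
    return tree_from_dict(data)


def save_tree(tree: ArterialTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1)
        fh.write("\n")
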