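"""Conversion between flat Petri nets and the matrix bundle used for simulation.

A :class:`MatrixBundle` is the simulation interchange object: ordered place and
transition id lists, the |P|x|T| input (Pre) and output (Post) multiplicity
matrices, the initial marking M0 and the vector of stochastic rate constants
c_j. The stoichiometry matrix S = Post - Pre is always derived, never stored.

Bundles serialize to a versioned JSON document (UTF-8, two-space indent,
sorted keys, row-major integer arrays) so that the same net always produces a
byte-identical file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import petri_model
from .errors import SchemaError, UnsupportedVersionError, ValidationError
from .petri_model import Arc, PetriNet, Place, Transition, flatten

__all__ = [
    "MatrixBundle",
    "BUNDLE_FORMAT_VERSION",
    "to_matrices",
    "from_matrices",
    "bundle_to_json",
    "bundle_from_json",
]

BUNDLE_FORMAT_VERSION = "1.0"


@dataclass(eq=False)
class MatrixBundle:
    place_ids: list[str]
    transition_ids: list[str]
    pre: np.ndarray
    post: np.ndarray
    initial_marking: np.ndarray
    rates: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.initial_marking = np.asarray(self.initial_marking, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.validate()

    @property
    def n_places(self) -> int:
        return len(self.place_ids)

    @property
    def n_transitions(self) -> int:
        return len(self.transition_ids)

    @property
    def stoichiometry(self) -> np.ndarray:
        """S = Post - Pre; column j is the state change of firing transition j."""
        return self.post - self.pre

    def validate(self) -> None:
        p, t = self.n_places, self.n_transitions
        if len(set(self.place_ids)) != p:
            raise ValidationError("duplicate place ids in bundle")
        if len(set(self.transition_ids)) != t:
            raise ValidationError("duplicate transition ids in bundle")
        for name, mat in (("Pre", self.pre), ("Post", self.post)):
            if mat.shape != (p, t):
                raise SchemaError(
                    f"{name} matrix has shape {mat.shape}, expected ({p}, {t})",
                    path=f"/{name.lower()}",
                )
            if (mat < 0).any():
                raise ValidationError(f"{name} entries must be >= 0")
        if self.initial_marking.shape != (p,):
            raise SchemaError(
                f"initial_marking has length {self.initial_marking.shape}, expected {p}",
                path="/initial_marking",
            )
        if (self.initial_marking < 0).any():
            raise ValidationError("initial marking entries must be >= 0")
        if self.rates.shape != (t,):
            raise SchemaError(
                f"rates has length {self.rates.shape}, expected {t}", path="/rates"
            )
        if (self.rates <= 0).any():
            raise ValidationError("rate constants must be > 0")

    def equals(self, other: "MatrixBundle") -> bool:
        return (
            self.place_ids == other.place_ids
            and self.transition_ids == other.transition_ids
            and np.array_equal(self.pre, other.pre)
            and np.array_equal(self.post, other.post)
            and np.array_equal(self.initial_marking, other.initial_marking)
            and np.array_equal(self.rates, other.rates)
        )


def to_matrices(net: PetriNet) -> MatrixBundle:
    """Convert a net (flattened internally) to its matrix bundle.

    Rows and columns are ordered lexicographically by id, so the conversion is
    deterministic regardless of insertion order.
    """
    flat = flatten(net)
    place_ids = sorted(flat.places)
    transition_ids = sorted(flat.transitions)
    p_index = {pid: i for i, pid in enumerate(place_ids)}
    t_index = {tid: j for j, tid in enumerate(transition_ids)}
    pre = np.zeros((len(place_ids), len(transition_ids)), dtype=np.int64)
    post = np.zeros_like(pre)
    for arc in flat.arcs:
        if arc.source in flat.places:
            pre[p_index[arc.source], t_index[arc.target]] += arc.multiplicity
        else:
            post[p_index[arc.target], t_index[arc.source]] += arc.multiplicity
    m0 = np.array([flat.places[pid].initial_tokens for pid in place_ids], dtype=np.int64)
    rates = np.array(
        [flat.transitions[tid].rate_constant for tid in transition_ids], dtype=np.float64
    )
    return MatrixBundle(place_ids, transition_ids, pre, post, m0, rates)


def from_matrices(bundle: MatrixBundle) -> PetriNet:
    """Reconstruct the flat net a bundle encodes; inverse of :func:`to_matrices`."""
    net = PetriNet(name=bundle.provenance.get("name", ""))
    for i, pid in enumerate(bundle.place_ids):
        net.places[pid] = Place(id=pid, initial_tokens=int(bundle.initial_marking[i]))
    for j, tid in enumerate(bundle.transition_ids):
        net.transitions[tid] = Transition(id=tid, rate_constant=float(bundle.rates[j]))
    for i, pid in enumerate(bundle.place_ids):
        for j, tid in enumerate(bundle.transition_ids):
            if bundle.pre[i, j]:
                net.arcs.append(Arc(pid, tid, int(bundle.pre[i, j])))
            if bundle.post[i, j]:
                net.arcs.append(Arc(tid, pid, int(bundle.post[i, j])))
    problems = petri_model.net_validate(net)
    if problems:
        raise ValidationError("bundle decodes to an invalid net: " + "; ".join(problems))
    return net


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def bundle_to_json(bundle: MatrixBundle) -> str:
    """Serialize to the versioned interchange document (byte-reproducible)."""
    doc = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "place_ids": bundle.place_ids,
        "transition_ids": bundle.transition_ids,
        "pre": bundle.pre.tolist(),
        "post": bundle.post.tolist(),
        "initial_marking": bundle.initial_marking.tolist(),
        "rates": bundle.rates.tolist(),
    }
    if bundle.provenance:
        doc["provenance"] = bundle.provenance
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def _require(doc: dict, key: str, kind, path: str):
    if key not in doc:
        raise SchemaError(f"missing required field {key!r}", path=f"{path}/{key}")
    value = doc[key]
    if not isinstance(value, kind):
        raise SchemaError(
            f"field {key!r} must be {kind.__name__}, got {type(value).__name__}",
            path=f"{path}/{key}",
        )
    return value


def _int_matrix(raw, rows: int, cols: int, path: str) -> np.ndarray:
    if not isinstance(raw, list) or len(raw) != rows:
        raise SchemaError(f"expected {rows} rows", path=path)
    out = np.zeros((rows, cols), dtype=np.int64)
    for i, row in enumerate(raw):
        if not isinstance(row, list) or len(row) != cols:
            raise SchemaError(f"expected {cols} columns", path=f"{path}/{i}")
        for j, value in enumerate(row):
            if not isinstance(value, int) or isinstance(value, bool):
                raise SchemaError("matrix entries must be integers", path=f"{path}/{i}/{j}")
            out[i, j] = value
    return out


def bundle_from_json(text: str) -> MatrixBundle:
    """Parse a bundle document; errors name the offending JSON path."""
    if not text.strip():
        raise SchemaError("empty document", path="/")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", path="/") from exc
    if not isinstance(doc, dict):
        raise SchemaError("top level must be an object", path="/")
    version = _require(doc, "format_version", str, "")
    if version.split(".")[0] != BUNDLE_FORMAT_VERSION.split(".")[0]:
        raise UnsupportedVersionError(
            f"format_version {version!r} not supported "
            f"(this library reads {BUNDLE_FORMAT_VERSION})",
            path="/format_version",
        )
    place_ids = _require(doc, "place_ids", list, "")
    transition_ids = _require(doc, "transition_ids", list, "")
    for path, ids in (("/place_ids", place_ids), ("/transition_ids", transition_ids)):
        for k, value in enumerate(ids):
            if not isinstance(value, str):
                raise SchemaError("ids must be strings", path=f"{path}/{k}")
    p, t = len(place_ids), len(transition_ids)
    pre = _int_matrix(_require(doc, "pre", list, ""), p, t, "/pre")
    post = _int_matrix(_require(doc, "post", list, ""), p, t, "/post")
    m0_raw = _require(doc, "initial_marking", list, "")
    if len(m0_raw) != p or not all(
        isinstance(v, int) and not isinstance(v, bool) for v in m0_raw
    ):
        raise SchemaError(f"expected {p} integers", path="/initial_marking")
    rates_raw = _require(doc, "rates", list, "")
    if len(rates_raw) != t or not all(
        isinstance(v, (int, float)) and not isinstance(v, bool) for v in rates_raw
    ):
        raise SchemaError(f"expected {t} numbers", path="/rates")
    provenance = doc.get("provenance", {})
    if not isinstance(provenance, dict):
        raise SchemaError("provenance must be an object", path="/provenance")
    try:
        return MatrixBundle(
            list(place_ids), list(transition_ids), pre, post,
            np.array(m0_raw, dtype=np.int64), np.array(rates_raw, dtype=np.float64),
            provenance=provenance,
        )
    except ValidationError as exc:
        raise SchemaError(str(exc), path="/") from exc
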