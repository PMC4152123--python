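"""Reusable net fragments (templates) and model composition.

A :class:`Template` is a parameterized Petri-net fragment with named binding
sites. Instantiating it substitutes bound ids for the sites (so they can be
shared with a host model) and prefixes all internal ids; :func:`compose`
merges a fragment — or a whole saved model — into a host net under a
namespace, unifying an explicit set of shared ids. Together these emulate the
building-block workflow of pathway modelling: publish a module once, wire it
into many models.

Built-in catalogue (see docs/methods.md for diagrams):

``AND``
    one transition consuming a token from each of two inputs, producing on
    the output — fires only when both inputs are supplied.
``OR``
    two transitions, one per input, sharing the output place.
``SOURCE`` / ``SINK``
    zero-order production into / first-order decay out of a place.
``REVERSIBLE_BINDING``
    A + B <-> AB as a forward (bind) and backward (release) transition pair.
``KINASE_SUBSTRATE``
    the catalytic phosphorylation motif: the kinase K is both input and
    output of the transition (its count is conserved) while one substrate
    token is converted into one phosphorylated-product token.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

from .errors import BindingError, CompositionError, ValidationError
from .io_formats import (
    PROJECT_FORMAT_VERSION,
    net_to_payload,
    payload_to_net,
)
from .errors import ParseError, SchemaError, UnsupportedVersionError
from .petri_model import (
    NAMESPACE_SEPARATOR,
    Arc,
    PetriNet,
    Place,
    Transition,
    net_validate,
)

import json

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateParameter",
    "Template",
    "instantiate",
    "compose",
    "builtin_templates",
    "read_template_json",
    "write_template_json",
]


@dataclass
class TemplateParameter:
    """A named binding site of a template."""

    name: str
    role: str  # "place" | "transition"
    required: bool = True


@dataclass
class Template:
    name: str
    parameters: list[TemplateParameter]
    body: PetriNet
    defaults: dict[str, float] = field(default_factory=dict)
    description: str = ""

    def parameter(self, name: str) -> TemplateParameter | None:
        for p in self.parameters:
            if p.name == name:
                return p
        return None


def instantiate(
    template: Template,
    bindings: dict[str, str],
    prefix: str = "",
) -> PetriNet:
    """Produce a concrete net fragment from a template.

    ``bindings`` maps site names to the ids the host will use for them;
    every internal (non-site) id is prefixed with ``prefix``. The result
    always passes :func:`net_validate`.
    """
    site_names = {p.name for p in template.parameters}
    unknown = set(bindings) - site_names
    if unknown:
        raise CompositionError(f"bindings name unknown site(s): {sorted(unknown)}")
    for p in template.parameters:
        if p.required and p.name not in bindings:
            raise BindingError(p.name)
    rename: dict[str, str] = {}
    for element_id in list(template.body.places) + list(template.body.transitions):
        if element_id in bindings:
            rename[element_id] = bindings[element_id]
        else:
            # internal ids and optional unbound sites get the namespace prefix
            rename[element_id] = prefix + element_id
    if len(set(rename.values())) != len(rename):
        raise CompositionError("bindings/prefix produce colliding ids")
    out = PetriNet(name=template.name, description=template.description)
    for pid, place in template.body.places.items():
        new = copy.deepcopy(place)
        new.id = rename[pid]
        new.contained = [rename.get(c, c) for c in new.contained]
        out.places[new.id] = new
    for tid, transition in template.body.transitions.items():
        new_t = copy.deepcopy(transition)
        new_t.id = rename[tid]
        if tid in template.defaults:
            new_t.rate_constant = template.defaults[tid]
        out.transitions[new_t.id] = new_t
    for arc in template.body.arcs:
        out.arcs.append(Arc(rename[arc.source], rename[arc.target], arc.multiplicity))
    problems = net_validate(out)
    if problems:
        raise ValidationError("instantiated fragment invalid: " + "; ".join(problems))
    return out


def compose(
    host: PetriNet,
    fragment: PetriNet,
    shared_ids: set[str] | None = None,
    prefix: str = "",
) -> PetriNet:
    """Merge ``fragment`` into ``host`` under a namespace (pure operation).

    Ids in ``shared_ids`` are unified between the two nets (they must exist
    in both with the same role; the host's element wins, with a logged note);
    every other fragment id is prefixed. The inputs are not modified.
    """
    shared_ids = set(shared_ids or ())
    for sid in shared_ids:
        host_role = "place" if sid in host.places else (
            "transition" if sid in host.transitions else None)
        frag_role = "place" if sid in fragment.places else (
            "transition" if sid in fragment.transitions else None)
        if host_role is None or frag_role is None:
            raise CompositionError(f"shared id {sid!r} missing from host or fragment")
        if host_role != frag_role:
            raise CompositionError(
                f"shared id {sid!r} is a {host_role} in the host "
                f"but a {frag_role} in the fragment"
            )
    out = copy.deepcopy(host)
    rename: dict[str, str] = {}
    for element_id in list(fragment.places) + list(fragment.transitions):
        if element_id in shared_ids:
            rename[element_id] = element_id
        else:
            new_id = prefix + element_id
            if new_id in out.places or new_id in out.transitions:
                raise CompositionError(f"id collision composing fragment: {new_id!r}")
            rename[element_id] = new_id
    for pid, place in fragment.places.items():
        if pid in shared_ids:
            logger.info("compose: shared id %r keeps the host's attributes", pid)
            continue
        new = copy.deepcopy(place)
        new.id = rename[pid]
        new.contained = [rename.get(c, c) for c in new.contained]
        out.places[new.id] = new
    for tid, transition in fragment.transitions.items():
        if tid in shared_ids:
            logger.info("compose: shared id %r keeps the host's attributes", tid)
            continue
        new_t = copy.deepcopy(transition)
        new_t.id = rename[tid]
        out.transitions[new_t.id] = new_t
    for arc in fragment.arcs:
        out.arcs.append(Arc(rename[arc.source], rename[arc.target], arc.multiplicity))
    problems = net_validate(out)
    if problems:
        raise ValidationError("composed net invalid: " + "; ".join(problems))
    return out


# ---------------------------------------------------------------------------
# Built-in catalogue
# ---------------------------------------------------------------------------

def _net(places, transitions, arcs) -> PetriNet:
    net = PetriNet()
    for pid in places:
        net.places[pid] = Place(id=pid)
    for tid, rate in transitions:
        net.transitions[tid] = Transition(id=tid, rate_constant=rate)
    for src, tgt in arcs:
        net.arcs.append(Arc(src, tgt, 1))
    return net


def builtin_templates() -> list[Template]:
    """The shipped module catalogue (logic gates and pathway motifs)."""
    P, T = "place", "transition"
    return [
        Template(
            name="AND",
            description="Output produced only when both inputs carry a token.",
            parameters=[TemplateParameter("in1", P), TemplateParameter("in2", P),
                        TemplateParameter("out", P)],
            body=_net(["in1", "in2", "out"], [("gate", 1.0)],
                      [("in1", "gate"), ("in2", "gate"), ("gate", "out")]),
            defaults={"gate": 1.0},
        ),
        Template(
            name="OR",
            description="Either input alone can produce the output.",
            parameters=[TemplateParameter("in1", P), TemplateParameter("in2", P),
                        TemplateParameter("out", P)],
            body=_net(["in1", "in2", "out"], [("gate1", 1.0), ("gate2", 1.0)],
                      [("in1", "gate1"), ("gate1", "out"),
                       ("in2", "gate2"), ("gate2", "out")]),
            defaults={"gate1": 1.0, "gate2": 1.0},
        ),
        Template(
            name="SOURCE",
            description="Zero-order production of a species.",
            parameters=[TemplateParameter("out", P)],
            body=_net(["out"], [("produce", 1.0)], [("produce", "out")]),
            defaults={"produce": 1.0},
        ),
        Template(
            name="SINK",
            description="First-order degradation of a species.",
            parameters=[TemplateParameter("in", P)],
            body=_net(["in"], [("degrade", 1.0)], [("in", "degrade")]),
            defaults={"degrade": 1.0},
        ),
        Template(
            name="REVERSIBLE_BINDING",
            description="A + B <-> AB complex formation and dissociation.",
            parameters=[TemplateParameter("a", P), TemplateParameter("b", P),
                        TemplateParameter("ab", P)],
            body=_net(["a", "b", "ab"], [("bind", 1.0), ("release", 1.0)],
                      [("a", "bind"), ("b", "bind"), ("bind", "ab"),
                       ("ab", "release"), ("release", "a"), ("release", "b")]),
            defaults={"bind": 1.0, "release": 1.0},
        ),
        Template(
            name="KINASE_SUBSTRATE",
            description=(
                "Catalytic phosphorylation: the kinase is consumed and "
                "re-produced by the same transition, so its token count is "
                "conserved while one substrate token becomes one product token."
            ),
            parameters=[TemplateParameter("kinase", P),
                        TemplateParameter("substrate", P),
                        TemplateParameter("product", P)],
            body=_net(["kinase", "substrate", "product"], [("phosphorylate", 1.0)],
                      [("kinase", "phosphorylate"), ("phosphorylate", "kinase"),
                       ("substrate", "phosphorylate"), ("phosphorylate", "product")]),
            defaults={"phosphorylate": 1.0},
        ),
    ]


def get_builtin(name: str) -> Template:
    for tpl in builtin_templates():
        if tpl.name == name:
            return tpl
    raise KeyError(f"no built-in template named {name!r}")


# ---------------------------------------------------------------------------
# Template files
# ---------------------------------------------------------------------------

def write_template_json(template: Template) -> str:
    """Serialize a template as a project-JSON document with a template wrapper."""
    doc = {
        "format_version": PROJECT_FORMAT_VERSION,
        "template": {
            "name": template.name,
            "description": template.description,
            "parameters": [
                {"name": p.name, "role": p.role, "required": p.required}
                for p in template.parameters
            ],
            "defaults": dict(sorted(template.defaults.items())),
            "body": net_to_payload(template.body),
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def read_template_json(text: str) -> Template:
    if not text.strip():
        raise ParseError("empty template document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("top level must be an object", path="/")
    version = doc.get("format_version")
    if not isinstance(version, str):
        raise SchemaError("missing or non-string format_version", path="/format_version")
    if version.split(".")[0] != PROJECT_FORMAT_VERSION.split(".")[0]:
        raise UnsupportedVersionError(
            f"format_version {version!r} not supported", path="/format_version"
        )
    wrapper = doc.get("template")
    if not isinstance(wrapper, dict):
        raise SchemaError("missing template wrapper", path="/template")
    parameters = []
    for k, raw in enumerate(wrapper.get("parameters", [])):
        if not isinstance(raw, dict) or "name" not in raw or "role" not in raw:
            raise SchemaError(
                "parameter must be an object with name and role",
                path=f"/template/parameters/{k}",
            )
        if raw["role"] not in ("place", "transition"):
            raise SchemaError(
                "role must be 'place' or 'transition'",
                path=f"/template/parameters/{k}/role",
            )
        parameters.append(TemplateParameter(
            name=raw["name"], role=raw["role"], required=bool(raw.get("required", True)),
        ))
    if "body" not in wrapper:
        raise SchemaError("missing template body", path="/template/body")
    body = payload_to_net(wrapper["body"], path="/template/body")
    return Template(
        name=str(wrapper.get("name", "")),
        description=str(wrapper.get("description", "")),
        parameters=parameters,
        body=body,
        defaults={str(k): float(v) for k, v in wrapper.get("defaults", {}).items()},
    )
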