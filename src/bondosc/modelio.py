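"""Declarative model files: parsing, validation and serialization.

Schema (version ``bondosc-model/1``), YAML canonical, JSON accepted::

    schema: bondosc-model/1
    constants: {RT: 1.0}
    species:
      - {name: Act, K: 1.0, amount: 1.0, chemostat: true}
      ...
    reactions:
      - {name: r0, kappa: 1.0, reactants: {Act: 1, E0: 1},
         products: {E1: 1, P: 1}}
      ...
    loop: {product: P, feedback_reactions: [r0]}

All schema violations are collected and reported together.  Serialization
round-trips bit-identically through the parser.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ModelValidationError
from .network import LoopSpec, Network, Reaction, Species

__all__ = ["SCHEMA_VERSION", "load_model", "dump_model", "model_to_dict",
           "model_from_dict"]

SCHEMA_VERSION = "bondosc-model/1"


def model_to_dict(network: Network, loop: LoopSpec = None) -> dict:
    doc = {
        "schema": SCHEMA_VERSION,
        "constants": {"RT": network.RT},
        "species": [
            {"name": s.name, "K": s.K, "amount": s.amount,
             "chemostat": bool(s.is_chemostat)}
            for s in network.species
        ],
        "reactions": [
            {"name": r.name, "kappa": r.kappa,
             "reactants": dict(r.reactants), "products": dict(r.products)}
            for r in network.reactions
        ],
    }
    if loop is not None:
        doc["loop"] = {
            "product": loop.product,
            "feedback_reactions": list(loop.feedback_reactions),
        }
    return doc


def _require(cond, errs, msg):
    if not cond:
        errs.append(msg)
    return cond


def model_from_dict(doc: dict):
    """Validate a parsed document and build (Network, LoopSpec or None)."""
    errs = []
    if not isinstance(doc, dict):
        raise ModelValidationError("model document must be a mapping")
    version = doc.get("schema")
    if version != SCHEMA_VERSION:
        errs.append(
            f"unsupported schema version {version!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    species = []
    for i, entry in enumerate(doc.get("species", []) or []):
        if not isinstance(entry, dict) or "name" not in entry:
            errs.append(f"species[{i}]: must be a mapping with a 'name'")
            continue
        try:
            species.append(Species(
                name=str(entry["name"]),
                K=float(entry.get("K", 1.0)),
                amount=float(entry.get("amount", 1.0)),
                is_chemostat=bool(entry.get("chemostat", False)),
            ))
        except (ModelValidationError, TypeError, ValueError) as exc:
            errs.append(f"species[{i}] ({entry.get('name')!r}): {exc}")
    if not species:
        errs.append("no species declared")
    reactions = []
    for i, entry in enumerate(doc.get("reactions", []) or []):
        if not isinstance(entry, dict) or "name" not in entry:
            errs.append(f"reactions[{i}]: must be a mapping with a 'name'")
            continue
        try:
            def side(key):
                raw = entry.get(key, {}) or {}
                if not isinstance(raw, dict):
                    raise ValueError(f"{key} must be a mapping")
                return {str(k): int(v) if float(v) == int(v) else float(v)
                        for k, v in raw.items()}

            reactions.append(Reaction(
                name=str(entry["name"]),
                kappa=float(entry.get("kappa", 1.0)),
                reactants=side("reactants"),
                products=side("products"),
            ))
        except (ModelValidationError, TypeError, ValueError) as exc:
            errs.append(f"reactions[{i}] ({entry.get('name')!r}): {exc}")
    if not reactions:
        errs.append("no reactions declared")
    network = None
    if species and reactions:
        try:
            network = Network(species, reactions,
                              RT=float((doc.get("constants") or {}).get("RT", 1.0)))
        except ModelValidationError as exc:
            errs.extend(exc.messages)
    loop = None
    loop_doc = doc.get("loop")
    if loop_doc is not None:
        if not isinstance(loop_doc, dict) or "product" not in loop_doc:
            errs.append("loop: must be a mapping with 'product' and "
                        "'feedback_reactions'")
        else:
            loop = LoopSpec(
                product=str(loop_doc["product"]),
                feedback_reactions=tuple(
                    loop_doc.get("feedback_reactions", []) or []),
            )
            if network is not None:
                try:
                    loop.validate(network)
                except ModelValidationError as exc:
                    errs.extend(exc.messages)
    if errs:
        raise ModelValidationError(errs)
    return network, loop


def load_model(path):
    """Parse a YAML (canonical) or JSON model file into (Network, LoopSpec)."""
    path = Path(path)
    if not path.exists():
        raise ModelValidationError(f"model file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return model_from_dict(doc)


def dump_model(network: Network, loop: LoopSpec = None, path=None,
               fmt: str = "yaml") -> str:
    """Serialize a model; returns the text and optionally writes ``path``."""
    doc = model_to_dict(network, loop)
    if fmt == "json":
        text = json.dumps(doc, indent=2, sort_keys=False) + "\n"
    elif fmt == "yaml":
        text = yaml.safe_dump(doc, sort_keys=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
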