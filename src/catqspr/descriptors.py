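"""Descriptor-name grammar, algebraic maps over tuple matrices, aggregation.

A descriptor name is an underscore-delimited token string, e.g.::

    I50_F_AB_nCi_2_M12_SS1_T_LGP[5]_s_MID

read as: aggregator I50 (median), linear form (F), atom-based (AB),
non-chiral (nCi), tuple order 2, Minkowski p=1.2 metric, simple-stochastic
normalization to the 1st matrix power, total scope (T), bond-path cutoff at
lag 5, softness weighting, MID suffix.  Per-atom local vertex invariants
(LOVIs) are obtained from linear, bilinear or quadratic maps between
property-weighted molecular vectors and the processed matrix; a statistical
aggregator turns the LOVI vector into one global molecular descriptor.

The F/B/Q form letters correspond to one, two and one weighting properties
respectively; ``AB`` and ``nCi`` are recorded verbatim in provenance and are
semantic no-ops in this implementation.  Only total scope is computed; local
(group/atom-type) scope parses but raises ``NotImplementedError``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .matrices import (
    BondGraph,
    CutoffScheme,
    TupleMatrix,
    apply_cutoff,
    bond_graph,
    normalize_matrix,
    pair_matrix,
    tuple_tensor,
)
from .structures import (
    PROPERTY_IDS,
    AtomicPropertyTable,
    Molecule,
    canonical_orientation,
    gasteiger_charges,
    load_property_tables,
)

__all__ = [
    "AGGREGATORS",
    "DescriptorSpec",
    "LoviVector",
    "parse_descriptor_name",
    "build_weight_vector",
    "compute_lovis",
    "aggregate_lovis",
    "compute_descriptor",
    "descriptor_table",
]

AGGREGATORS = ("S", "GM", "VC", "I50", "AM", "N1", "N2", "MAX", "MIN", "V", "RA")
_FORMS = {"F": "linear", "B": "bilinear", "Q": "quadratic"}
_FORM_TOKENS = {v: k for k, v in _FORMS.items()}
_NORM_RE = re.compile(r"^(NS|SS|DS|MP)(\d*)$")
_CUTOFF_RE = re.compile(r"^(LGP|LGL)\[([^\]]+)\]$")
_ANGULAR_TOKENS = ("ANG", "DIH")


@dataclass(frozen=True)
class DescriptorSpec:
    """Parsed form of a descriptor name; round-trips through :meth:`name`."""

    aggregator: str
    form: str               # linear | bilinear | quadratic
    tuple_order: int
    metric_id: str
    normalization: str      # NS | SS | DS | MP
    power: int
    scope: str              # "total" or the verbatim local token
    cutoff: CutoffScheme
    weights: tuple[str, ...]
    flags: tuple[str, ...] = ("AB", "nCi")
    suffix: str = "MID"

    def __post_init__(self):
        n_expected = 2 if self.form == "bilinear" else 1
        if len(self.weights) != n_expected:
            raise ConfigurationError(
                f"{self.form} form requires {n_expected} weighting "
                f"propert{'ies' if n_expected > 1 else 'y'}, got "
                f"{self.weights}")

    def name(self) -> str:
        scope_tok = "T" if self.scope == "total" else self.scope
        return "_".join([
            self.aggregator, _FORM_TOKENS[self.form], *self.flags,
            str(self.tuple_order), self.metric_id,
            f"{self.normalization}{self.power}", scope_tok,
            self.cutoff.token(), "-".join(self.weights), self.suffix,
        ])


@dataclass(frozen=True)
class LoviVector:
    """Per-atom local vertex invariants plus the spec that produced them."""

    values: np.ndarray
    provenance: DescriptorSpec

    @property
    def total(self) -> float:
        """Full algebraic-form value: the sum of the LOVIs."""
        return float(self.values.sum())


def parse_descriptor_name(name: str) -> DescriptorSpec:
    """Parse an underscore-delimited descriptor name into a DescriptorSpec.

    Raises :class:`ConfigurationError` naming the offending token and its
    1-based position.  En dashes inside cutoff windows are accepted.
    """
    tokens = name.strip().split("_")
    if len(tokens) != 11:
        raise ConfigurationError(
            f"descriptor name must have 11 underscore-separated tokens, "
            f"got {len(tokens)}: {name!r}")

    def bad(pos, tok, why):
        return ConfigurationError(
            f"token {tok!r} at position {pos}: {why} (name {name!r})")

    agg, form_tok, f1, f2, order_tok, metric, norm_tok, scope_tok, \
        cut_tok, weight_tok, suffix = tokens
    if agg not in AGGREGATORS:
        raise bad(1, agg, f"unknown aggregator; valid: {AGGREGATORS}")
    if form_tok not in _FORMS:
        raise bad(2, form_tok, "form must be F (linear), B (bilinear) or "
                               "Q (quadratic)")
    if order_tok not in ("2", "3", "4"):
        raise bad(5, order_tok, "tuple order must be 2, 3 or 4")
    m = _NORM_RE.match(norm_tok)
    if not m:
        raise bad(7, norm_tok, "expected NS/SS/DS/MP with optional power digit")
    norm, power = m.group(1), int(m.group(2) or 1)
    scope = "total" if scope_tok == "T" else scope_tok
    cutoff = _parse_cutoff(cut_tok, pos=9, name=name)
    weights = tuple(weight_tok.split("-"))
    for w in weights:
        if w not in PROPERTY_IDS:
            raise bad(10, weight_tok, f"unknown weighting property {w!r}")
    if suffix != "MID":
        raise bad(11, suffix, "expected literal suffix 'MID'")
    return DescriptorSpec(
        aggregator=agg, form=_FORMS[form_tok], tuple_order=int(order_tok),
        metric_id=metric, normalization=norm, power=power, scope=scope,
        cutoff=cutoff, weights=weights, flags=(f1, f2))


def _parse_cutoff(token: str, pos: int, name: str) -> CutoffScheme:
    if token == "KA":
        return CutoffScheme("KA")
    if any(token.startswith(t) for t in _ANGULAR_TOKENS):
        raise NotImplementedError(
            f"angular cutoff {token!r} is recognized but not implemented")
    m = _CUTOFF_RE.match(token)
    if not m:
        raise ConfigurationError(
            f"token {token!r} at position {pos}: expected KA, LGP[k] or "
            f"LGL[a-b] (name {name!r})")
    kind, arg = m.groups()
    if kind == "LGP":
        return CutoffScheme("LGP", lag_max=int(arg))
    parts = re.split(r"[-–—]", arg)  # hyphen, en dash, em dash
    if len(parts) != 2:
        raise ConfigurationError(
            f"token {token!r} at position {pos}: LGL window needs two bounds")
    return CutoffScheme("LGL", window=(float(parts[0]), float(parts[1])))


# ---------------------------------------------------------------------------
# Weight vectors and LOVI maps
# ---------------------------------------------------------------------------

def build_weight_vector(mol: Molecule, property_id: str,
                        tables: Mapping[str, AtomicPropertyTable] | None = None,
                        charge_cache: dict | None = None) -> np.ndarray:
    """Per-atom values of one weighting property, in atom order.

    Property ``c`` is the Gasteiger-Marsili charge, computed once per
    molecule with default PEOE settings (cacheable via ``charge_cache``).
    """
    if property_id == "c":
        if charge_cache is not None and id(mol) in charge_cache:
            return charge_cache[id(mol)]
        q = gasteiger_charges(mol)
        if charge_cache is not None:
            charge_cache[id(mol)] = q
        return q
    tables = tables if tables is not None else load_property_tables()
    from .structures import property_lookup
    return np.array([property_lookup(tables, e, property_id)
                     for e in mol.elements])


def _processed_matrix(mol: Molecule, spec: DescriptorSpec) -> TupleMatrix:
    """canonical frame -> metric -> cutoff -> normalization -> power."""
    # frame-dependent metrics (Minkowski p != 2, Chebyshev) are evaluated in
    # the principal-axes frame so descriptors are rigid-motion invariant
    mol = canonical_orientation(mol)
    if spec.tuple_order == 2:
        M = pair_matrix(mol, spec.metric_id)
    else:
        M = tuple_tensor(mol, spec.tuple_order, spec.metric_id)
    graph = bond_graph(mol) if spec.cutoff.kind == "LGP" else None
    dists = mol.distance_matrix() if spec.cutoff.kind == "LGL" else None
    M = apply_cutoff(M, spec.cutoff, graph=graph, distances=dists)
    # zero rows are kept (not an error): aggressive cutoffs legitimately
    # disconnect atoms, whose LOVI is then 0.
    return normalize_matrix(M, spec.normalization, power=spec.power,
                            zero_rows="keep")


def compute_lovis(mol: Molecule, spec: DescriptorSpec,
                  tables: Mapping[str, AtomicPropertyTable] | None = None,
                  charge_cache: dict | None = None) -> LoviVector:
    """Local vertex invariants of one molecule under one descriptor spec.

    With processed array ``g`` and weight vectors x (and y for bilinear):

    * linear     ``L_i = sum_j g_ij x_j`` (unit probe row),
    * quadratic  ``L_i = x_i sum_j g_ij x_j``,
    * bilinear   ``L_i = x_i sum_j g_ij y_j``;

    order-3/4 tensors extend the sums over the remaining tuple indices, the
    same weight vector applied at every summed position.  The LOVI sum
    equals the full bilinear/quadratic/linear form value by construction.
    """
    if mol.n_atoms < spec.tuple_order:
        raise DomainError(
            f"molecule {mol.id!r} has {mol.n_atoms} atoms; tuple order "
            f"{spec.tuple_order} requires at least that many")
    if spec.scope != "total":
        raise NotImplementedError(
            f"local scope {spec.scope!r} is parsed but not computed")
    g = _processed_matrix(mol, spec).entries
    x = build_weight_vector(mol, spec.weights[0], tables, charge_cache)
    y = (build_weight_vector(mol, spec.weights[1], tables, charge_cache)
         if spec.form == "bilinear" else x)

    if spec.tuple_order == 2:
        inner = g @ y
    elif spec.tuple_order == 3:
        inner = np.einsum("ijk,j,k->i", g, y, y)
    else:
        inner = np.einsum("ijkl,j,k,l->i", g, y, y, y)

    # linear: unit probe on the leading index, the weight on summed positions
    L = inner if spec.form == "linear" else x * inner
    return LoviVector(values=np.asarray(L, dtype=float), provenance=spec)


def aggregate_lovis(L: LoviVector | np.ndarray, aggregator: str) -> float:
    """Collapse a LOVI vector to one global descriptor value.

    S=sum, AM=mean, GM=geometric mean of |L| (0 if any entry is 0),
    VC=sample std / |mean| (NaN when the mean is 0), I50=median,
    N1/N2=Minkowski 1- and 2-norms, MAX/MIN, V=sample variance, RA=range.
    """
    v = L.values if isinstance(L, LoviVector) else np.asarray(L, dtype=float)
    if v.size == 0:
        raise DomainError("cannot aggregate an empty LOVI vector")
    if aggregator == "S":
        return float(v.sum())
    if aggregator == "AM":
        return float(v.mean())
    if aggregator == "GM":
        a = np.abs(v)
        if np.any(a == 0):
            return 0.0
        return float(np.exp(np.log(a).mean()))
    if aggregator == "VC":
        mu = v.mean()
        if mu == 0:
            return float("nan")
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        return float(sd / abs(mu))
    if aggregator == "I50":
        return float(np.median(v))
    if aggregator == "N1":
        return float(np.abs(v).sum())
    if aggregator == "N2":
        return float(np.sqrt((v**2).sum()))
    if aggregator == "MAX":
        return float(v.max())
    if aggregator == "MIN":
        return float(v.min())
    if aggregator == "V":
        return float(v.var(ddof=1)) if v.size > 1 else 0.0
    if aggregator == "RA":
        return float(v.max() - v.min())
    raise ConfigurationError(
        f"unknown aggregator {aggregator!r}; valid: {AGGREGATORS}")


def compute_descriptor(mol: Molecule, spec: DescriptorSpec | str,
                       tables: Mapping[str, AtomicPropertyTable] | None = None,
                       charge_cache: dict | None = None) -> float:
    """One global descriptor value for one molecule."""
    if isinstance(spec, str):
        spec = parse_descriptor_name(spec)
    L = compute_lovis(mol, spec, tables, charge_cache)
    return aggregate_lovis(L, spec.aggregator)


def descriptor_table(mols: Sequence[Molecule],
                     specs: Sequence[DescriptorSpec | str],
                     tables: Mapping[str, AtomicPropertyTable] | None = None,
                     ) -> pd.DataFrame:
    """Molecule-by-descriptor value table.

    Rows are molecule ids, columns descriptor names.  Per-cell failures are
    recorded as NaN with the reason kept in ``result.attrs['failures']``
    (``(mol_id, descriptor_name) -> message``), never as silent zeros.
    """
    parsed = [parse_descriptor_name(s) if isinstance(s, str) else s
              for s in specs]
    names = [s.name() for s in parsed]
    cache: dict = {}
    failures: dict[tuple[str, str], str] = {}
    rows = []
    for mol in mols:
        row = []
        for spec, name in zip(parsed, names):
            try:
                row.append(compute_descriptor(mol, spec, tables, cache))
            except Exception as exc:  # noqa: BLE001 - per-cell flagging
                failures[(mol.id, name)] = f"{type(exc).__name__}: {exc}"
                row.append(np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, index=[m.id for m in mols], columns=names)
    df.index.name = "molecule"
    df.attrs["failures"] = failures
    return df
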