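"""NOR-only circuit synthesis, repressor assignment and steady-state
prediction.

Transcriptional NOT/NOR gates are repressor-based inverters whose inputs
and output are promoters.  Any truth table can be computed with NOR/NOT
gates alone: the table is minimized to a product-of-sums and converted by
De Morgan's laws into a NOR/NOT netlist with fan-in capped at two (one
gate integrates at most two input promoters).

Steady state is predicted per input state by propagating promoter
activities (RPU_G) through each gate's Hill response function, in
topological order.  Alongside the output, the engine accounts for the
circuit's draw on host resources (total RNAP flux = sum of gate-input and
sensor-output activities) and its predicted growth impact.

Truth-table row order: rows enumerate the input states in binary counting
order with input 1 as the most significant bit; a hex code names a table
most-significant-row-first, i.e. the first row (all inputs 0) maps to the
highest-order bit of the code.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from graphlib import CycleError, TopologicalSorter

from sympy import Symbol, symbols
from sympy.logic import POSform
from sympy.logic.boolalg import And, Not, Or

from .library import ConversionConstants, GateLibrary, GateModel
from .quantitation import hill_response


# ---------------------------------------------------------------------------
# Truth tables


@dataclass(frozen=True)
class TruthTable:
    n_inputs: int
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.n_inputs <= 4:
            raise ValueError("n_inputs must be in [1, 4]")
        if len(self.outputs) != 2**self.n_inputs:
            raise ValueError("outputs length must be 2^n_inputs")
        if any(b not in (0, 1) for b in self.outputs):
            raise ValueError("outputs must be bits")

    @classmethod
    def from_hex(cls, code: str | int, n_inputs: int) -> "TruthTable":
        value = int(code, 16) if isinstance(code, str) else int(code)
        n_rows = 2**n_inputs
        if not 0 <= value < 2**n_rows:
            raise ValueError(f"hex code out of range for {n_inputs} inputs")
        outputs = tuple((value >> (n_rows - 1 - i)) & 1 for i in range(n_rows))
        return cls(n_inputs=n_inputs, outputs=outputs)

    @property
    def is_constant(self) -> bool:
        return len(set(self.outputs)) == 1

    def hex(self) -> str:
        value = 0
        for b in self.outputs:
            value = (value << 1) | b
        return f"0x{value:0{max(1, 2 ** self.n_inputs // 4)}X}"


def enumerate_states(n: int) -> list[tuple[int, ...]]:
    """All 2^n input-bit tuples in binary counting order, 00...0 first."""
    if not 1 <= n <= 4:
        raise ValueError("arity must be in [1, 4]")
    return list(itertools.product((0, 1), repeat=n))


# ---------------------------------------------------------------------------
# Netlists


@dataclass(frozen=True)
class GateNode:
    id: str
    kind: str  # "NOT" | "NOR"
    inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("NOT", "NOR"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "NOT" and len(self.inputs) != 1:
            raise ValueError("NOT gate takes exactly 1 input")
        if self.kind == "NOR" and len(self.inputs) != 2:
            raise ValueError("NOR gate takes exactly 2 inputs")


@dataclass(frozen=True)
class CircuitNetlist:
    sensor_nodes: tuple[str, ...]
    gate_nodes: tuple[GateNode, ...]
    output_node: str

    def __post_init__(self) -> None:
        ids = set(self.sensor_nodes) | {g.id for g in self.gate_nodes}
        if len(ids) != len(self.sensor_nodes) + len(self.gate_nodes):
            raise ValueError("duplicate node identifier")
        for g in self.gate_nodes:
            for src in g.inputs:
                if src not in ids:
                    raise ValueError(f"gate {g.id} wired to unknown node {src!r}")
        if self.output_node not in {g.id for g in self.gate_nodes}:
            raise ValueError("output node must be a gate")
        self.topological_gates()  # raises on cycles
        # every gate must feed the output
        needed: set[str] = set()
        stack = [self.output_node]
        by_id = {g.id: g for g in self.gate_nodes}
        while stack:
            nid = stack.pop()
            if nid in needed or nid not in by_id:
                continue
            needed.add(nid)
            stack.extend(by_id[nid].inputs)
        unreachable = {g.id for g in self.gate_nodes} - needed
        if unreachable:
            raise ValueError(f"gates not feeding the output: {sorted(unreachable)}")

    def topological_gates(self) -> list[GateNode]:
        ts = TopologicalSorter(
            {g.id: [s for s in g.inputs if s not in self.sensor_nodes] for g in self.gate_nodes}
        )
        try:
            order = list(ts.static_order())
        except CycleError as e:
            raise ValueError("netlist contains a cycle") from e
        by_id = {g.id: g for g in self.gate_nodes}
        return [by_id[nid] for nid in order]

    @property
    def n_gates(self) -> int:
        return len(self.gate_nodes)

    def with_sensors(self, names: tuple[str, ...] | list[str]) -> "CircuitNetlist":
        """Rename the sensor nodes (positionally) to library sensor names."""
        names = tuple(names)
        if len(names) != len(self.sensor_nodes):
            raise ValueError("sensor name count mismatch")
        rename = dict(zip(self.sensor_nodes, names))
        gates = tuple(
            GateNode(g.id, g.kind, tuple(rename.get(s, s) for s in g.inputs))
            for g in self.gate_nodes
        )
        return CircuitNetlist(names, gates, self.output_node)


def boolean_eval(net: CircuitNetlist, state: tuple[int, ...]) -> int:
    """Evaluate the netlist digitally (NOR = not-or) for one input state."""
    if len(state) != len(net.sensor_nodes):
        raise ValueError("state arity does not match sensor count")
    values: dict[str, int] = dict(zip(net.sensor_nodes, state))
    for g in net.topological_gates():
        ins = [values[s] for s in g.inputs]
        values[g.id] = int(not any(ins))  # NOT is 1-input NOR
    return values[net.output_node]


def boolean_truth_table(net: CircuitNetlist) -> TruthTable:
    n = len(net.sensor_nodes)
    return TruthTable(n, tuple(boolean_eval(net, s) for s in enumerate_states(n)))


# ---------------------------------------------------------------------------
# Synthesis


class _Builder:
    def __init__(self, n_inputs: int):
        self.sensors = tuple(f"x{i + 1}" for i in range(n_inputs))
        self.gates: list[GateNode] = []
        self._not_cache: dict[str, str] = {}

    def _new(self, kind: str, inputs: tuple[str, ...]) -> str:
        gid = f"g{len(self.gates) + 1}"
        self.gates.append(GateNode(gid, kind, inputs))
        return gid

    def not_of(self, src: str) -> str:
        if src not in self._not_cache:
            self._not_cache[src] = self._new("NOT", (src,))
        return self._not_cache[src]

    def nor2(self, a: str, b: str) -> str:
        return self._new("NOR", (a, b))

    def or2(self, a: str, b: str) -> str:
        return self.not_of(self.nor2(a, b))

    def nor_many(self, nodes: list[str]) -> str:
        """NOR of k >= 2 nodes with fan-in-2 gates: OR-chain the first k-1,
        then one final NOR."""
        if len(nodes) == 1:
            return self.not_of(nodes[0])
        acc = nodes[0]
        for nxt in nodes[1:-1]:
            acc = self.or2(acc, nxt)
        return self.nor2(acc, nodes[-1])


def _clauses(expr) -> list[list[tuple[int, bool]]]:
    """Flatten a sympy POS expression into clauses of (var_index, negated)."""

    def literal(lit) -> tuple[int, bool]:
        if isinstance(lit, Not):
            sym = lit.args[0]
            neg = True
        else:
            sym = lit
            neg = False
        if not isinstance(sym, Symbol):
            raise ValueError(f"unexpected literal {lit}")
        return int(str(sym)[1:]) - 1, neg

    clause_exprs = list(expr.args) if isinstance(expr, And) else [expr]
    clauses = []
    for c in clause_exprs:
        lits = list(c.args) if isinstance(c, Or) else [c]
        clauses.append(sorted(literal(l) for l in lits))
    return clauses


def synthesize_nor(t: TruthTable) -> CircuitNetlist:
    """Synthesize a NOR/NOT-only netlist computing the truth table.

    The table is minimized to a product-of-sums (exact Quine-McCluskey at
    arity <= 4); each sum clause C is realized as its complement
    not-C = NOR(literals), and the conjunction of clauses as
    AND_i C_i = NOR_i(not-C_i), so only NOR/NOT gates appear.  Wide ORs/NORs
    are decomposed into fan-in-2 trees.  The returned netlist is verified
    against the table by exhaustive Boolean evaluation before returning.
    """
    if t.is_constant:
        raise ValueError("constant truth table: no circuit needed")
    vars_ = symbols(f"x1:{t.n_inputs + 1}")
    if not isinstance(vars_, tuple):
        vars_ = (vars_,)
    minterms = [i for i, b in enumerate(t.outputs) if b]
    expr = POSform(list(vars_), minterms)
    clauses = _clauses(expr)

    b = _Builder(t.n_inputs)

    def lit_node(idx: int, negated: bool) -> str:
        sensor = b.sensors[idx]
        return b.not_of(sensor) if negated else sensor

    # node computing the complement of each clause
    comp_nodes: list[str] = []
    for clause in clauses:
        if len(clause) == 1:
            idx, neg = clause[0]
            # complement of a single literal
            comp_nodes.append(b.sensors[idx] if neg else b.not_of(b.sensors[idx]))
        else:
            comp_nodes.append(b.nor_many([lit_node(i, n) for i, n in clause]))

    if len(comp_nodes) == 1:
        out = b.not_of(comp_nodes[0])
    else:
        out = b.nor_many(comp_nodes)

    net = CircuitNetlist(b.sensors, tuple(b.gates), out)
    if boolean_truth_table(net).outputs != t.outputs:  # pragma: no cover
        raise AssertionError("synthesized netlist does not reproduce the table")
    return net


# ---------------------------------------------------------------------------
# Analog steady-state prediction


@dataclass(frozen=True)
class EngineConfig:
    """Semantics of two-input gates and design-feasibility settings.

    gate_semantics: "split" (two repressor copies, each driven by one input
        promoter; effective input = sum of activities) or "tandem" (two
        promoters in series upstream of one repressor gene; the upstream
        promoter is attenuated by ``tandem_alpha`` to model roadblocking;
        alpha = 1 recovers the ordinary additive model).
    growth_aggregation: "product" multiplies the per-gate growth factors
        (multiplicative-burden model, default); "min" takes the worst gate.
    """

    gate_semantics: str = "split"
    tandem_alpha: float = 1.0
    growth_cutoff: float = 0.75
    growth_aggregation: str = "product"

    def __post_init__(self) -> None:
        if self.gate_semantics not in ("split", "tandem"):
            raise ValueError("gate_semantics must be 'split' or 'tandem'")
        if not 0.0 <= self.tandem_alpha <= 1.0:
            raise ValueError("tandem_alpha must be in [0, 1]")
        if not 0.0 <= self.growth_cutoff <= 1.0:
            raise ValueError("growth_cutoff must be in [0, 1]")
        if self.growth_aggregation not in ("product", "min"):
            raise ValueError("growth_aggregation must be 'product' or 'min'")


@dataclass(frozen=True)
class Assignment:
    """Injective mapping gate id -> repressor name."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        reps = list(self.mapping.values())
        if len(set(reps)) != len(reps):
            raise ValueError("assignment must be injective (each repressor used once)")


@dataclass(frozen=True)
class StatePrediction:
    state: tuple[int, ...]
    node_outputs: dict[str, float]  # RPU_G per sensor/gate node
    output: float  # RPU_G at the circuit output promoter
    total_flux: float  # RPU_G, gates' inputs + sensors' outputs
    growth_score: float
    output_repressor: str


def _check_assignment(net: CircuitNetlist, asg: Assignment, lib: GateLibrary) -> None:
    gate_ids = {g.id for g in net.gate_nodes}
    if set(asg.mapping) != gate_ids:
        missing = gate_ids - set(asg.mapping)
        raise ValueError(f"assignment must cover every gate (missing {sorted(missing)})")
    known = set(lib.repressors)
    for rep in asg.mapping.values():
        if rep not in known:
            raise KeyError(f"repressor {rep!r} not in library")


def predict_state(
    net: CircuitNetlist,
    asg: Assignment,
    lib: GateLibrary,
    state: tuple[int, ...],
    cfg: EngineConfig = EngineConfig(),
) -> StatePrediction:
    """Predict the analog steady state of every node for one input state.

    Sensors emit y_min (bit 0) or y_max (bit 1).  Each gate sees an
    effective input activity x_eff — the sum of its input promoters under
    split semantics, or downstream + alpha * upstream under tandem
    semantics (the first listed input is the upstream promoter) — and
    outputs the Hill response of its assigned repressor at x_eff.
    """
    _check_assignment(net, asg, lib)
    if len(state) != len(net.sensor_nodes):
        raise ValueError("state arity does not match sensor count")
    acts: dict[str, float] = {}
    for name, bit in zip(net.sensor_nodes, state):
        s = lib.sensor(name)
        acts[name] = s.y_max if bit else s.y_min

    sensor_flux = sum(acts.values())
    gate_flux = 0.0
    growth_factors: list[float] = []
    out_rep = asg.mapping[net.output_node]
    for g in net.topological_gates():
        ins = [acts[s] for s in g.inputs]
        if len(ins) == 1:
            x_eff = ins[0]
        elif cfg.gate_semantics == "split":
            x_eff = ins[0] + ins[1]
        else:  # tandem: first listed input is upstream, attenuated by alpha
            x_eff = ins[1] + cfg.tandem_alpha * ins[0]
        model = lib.gate_by_repressor(asg.mapping[g.id])
        acts[g.id] = hill_response(model.response, x_eff)
        gate_flux += x_eff
        growth_factors.append(min(max(model.growth(x_eff), 0.0), 1.0))

    if cfg.growth_aggregation == "product":
        growth = math.prod(growth_factors) if growth_factors else 1.0
    else:
        growth = min(growth_factors) if growth_factors else 1.0

    return StatePrediction(
        state=tuple(state),
        node_outputs=acts,
        output=acts[net.output_node],
        total_flux=gate_flux + sensor_flux,
        growth_score=growth,
        output_repressor=out_rep,
    )


def predict_all_states(
    net: CircuitNetlist,
    asg: Assignment,
    lib: GateLibrary,
    cfg: EngineConfig = EngineConfig(),
) -> list[StatePrediction]:
    return [
        predict_state(net, asg, lib, s, cfg)
        for s in enumerate_states(len(net.sensor_nodes))
    ]


def circuit_score(predictions: list[StatePrediction], t: TruthTable) -> float:
    """min(ON-state outputs) / max(OFF-state outputs); > 1 means the two
    digital levels are separable at the output promoter."""
    if t.is_constant:
        raise ValueError("constant truth table has no ON/OFF separation")
    by_state = {p.state: p.output for p in predictions}
    states = enumerate_states(t.n_inputs)
    if set(states) - set(by_state):
        raise ValueError("predictions must cover all states")
    on = [by_state[s] for s, b in zip(states, t.outputs) if b]
    off = [by_state[s] for s, b in zip(states, t.outputs) if not b]
    return min(on) / max(off)


@dataclass(frozen=True)
class AssignmentResult:
    assignment: Assignment
    score: float
    predictions: list[StatePrediction]
    growth_infeasible: bool
    n_examined: int


def assign_gates(
    net: CircuitNetlist,
    lib: GateLibrary,
    cfg: EngineConfig = EngineConfig(),
) -> AssignmentResult:
    """Exhaustively search injective repressor assignments.

    Candidates whose worst per-state growth score falls below
    ``cfg.growth_cutoff`` are discarded; among survivors the assignment
    maximizing the circuit score wins, with ties broken by lexicographic
    assignment order (repressor tuples in sorted order).  If no assignment
    survives the growth filter, the best-scoring infeasible one is returned
    flagged ``growth_infeasible``.
    """
    gate_ids = [g.id for g in net.topological_gates()]
    reps = sorted(lib.repressors)
    if len(gate_ids) > len(reps):
        raise ValueError(
            f"{len(gate_ids)} gates exceed {len(reps)} available repressors"
        )
    target = boolean_truth_table(net)

    best_ok: tuple[float, AssignmentResult] | None = None
    best_any: tuple[float, AssignmentResult] | None = None
    n_examined = 0
    for perm in itertools.permutations(reps, len(gate_ids)):
        n_examined += 1
        asg = Assignment(dict(zip(gate_ids, perm)))
        preds = predict_all_states(net, asg, lib, cfg)
        score = circuit_score(preds, target)
        feasible = min(p.growth_score for p in preds) >= cfg.growth_cutoff
        res = AssignmentResult(asg, score, preds, not feasible, 0)
        if feasible and (best_ok is None or score > best_ok[0]):
            best_ok = (score, res)
        if best_any is None or score > best_any[0]:
            best_any = (score, res)
    chosen = best_ok if best_ok is not None else best_any
    assert chosen is not None
    return replace(chosen[1], n_examined=n_examined)


def total_flux_report(
    predictions: list[StatePrediction],
    c: ConversionConstants = ConversionConstants(),
):
    """Per-state resource-draw table.

    Total flux (gate inputs + sensor outputs) reported in RPU_G, in RPU
    (divided by the RPU_G-per-RPU divisor) and in absolute RNAP/s
    (multiplied by flux-per-RPU-per-DNA times the landing-pad copy number).
    Returns a tidy :class:`pandas.DataFrame`.
    """
    import pandas as pd

    rows = []
    per_dna = c.flux_per_rpu_per_dna * c.landing_pad_copy_number
    for p in predictions:
        rows.append(
            {
                "state": "".join(map(str, p.state)),
                "flux_rpug": p.total_flux,
                "flux_rpu": p.total_flux / c.rpug_per_rpu,
                "flux_rnap_per_s": p.total_flux * per_dna,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LognormalPrediction:
    """Predicted single-cell output distribution: lognormal with the given
    median and log-scale sigma (sigma = sqrt(ln(1 + CV^2)))."""

    median: float
    sigma_log: float

    def sample(self, n: int, rng) -> "object":
        import numpy as np

        z = rng.standard_normal(n)
        return self.median * np.exp(self.sigma_log * z)


def predict_distribution(p: StatePrediction, lib: GateLibrary) -> LognormalPrediction:
    """Population-level stand-in for the predicted output distribution:
    lognormal centered at the predicted median with the output gate's
    cytometry CV."""
    cv = lib.gate_by_repressor(p.output_repressor).noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return LognormalPrediction(median=p.output, sigma_log=sigma)
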