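"""Query an annotated collection: gatekeeper + binding-mode search.

Annotates a small engineered collection, then asks for structures with a
threonine gatekeeper whose ligand occupies the front cleft and gate area
but not the back cleft, and exports the hits as CSV.
"""

from kinpocket import Query, annotate_monomer, evaluate_query, export_results
from kinpocket.fixtures import DesignedContact, FixtureSpec, generate_complex

front_gate = (DesignedContact(47, "hbond_donor"),
              DesignedContact(45, "hydrophobic"))
specs = [
    FixtureSpec(source_id="hit1", contacts=front_gate,
                occupy_subpockets=("FP-I", "BP-I-A")),
    FixtureSpec(source_id="hit2", contacts=front_gate,
                occupy_subpockets=("FP-I", "BP-I-A"), waters=("I4", "I5")),
    FixtureSpec(source_id="bulky_gk", contacts=front_gate,
                occupy_subpockets=("FP-I", "BP-I-A"),
                pocket_substitutions={45: "M"}),
    FixtureSpec(source_id="back_binder", contacts=front_gate,
                occupy_subpockets=("FP-I", "BP-I-A", "BP-II-in")),
    FixtureSpec(source_id="apo"),
]
complexes = [generate_complex(s) for s in specs]
records = [annotate_monomer(c.monomer, dictionary=c.dictionary()) for c in complexes]

query = Query(pocket_composition={45: "T"},
              subpockets_present=("front_cleft", "gate_area"),
              subpockets_absent=("back_cleft",))
hits = evaluate_query(records, query)
print(f"{len(hits)} of {len(records)} records match:")
for rec in hits:
    print(f"  {rec.entry_id}: gatekeeper={rec.residue_at(45)}, "
          f"subpockets={sorted(k for k, v in rec.subpockets.items() if v)}")
print()
print(export_results(hits))

# Only the two T-gatekeeper front+gate binders survive: the methionine
# gatekeeper fails the composition clause, the back-cleft binder fails
# the negative subpocket clause, and the apo record has no flags at all.
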