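"""Market-name precision and worst-case conservation status.

Shows the three per-name questions the audit asks: what may legally be
sold under a name (lookup/alias resolution), whether the name is precise
or ambiguous, and which IUCN category a multi-species barcode inherits
(the worst case among its candidates, with assessed categories always
beating Not-Applicable/Data-Deficient).
"""

import seafood_audit as sa

bundle = sa.load_fixture("finfish")
authority, registry = bundle.authority, bundle.status_registry

for raw in ("Unagi", "Red Tuna", "Atlantic Salmon", "Snapper", "Sea Eel"):
    entry = authority.lookup(raw)
    line = f"{raw!r:20} -> {entry.list_status}"
    if entry.list_status == "alias":
        line += f" (reads as {authority.resolve(raw).market_name!r})"
    line += f", {authority.classify_precision(raw)}"
    print(line)

print()
candidates = {"Thunnus albacares", "Thunnus obesus", "Simulatus unlisted"}
assignment = registry.assign_status(candidates)
print(f"barcode matched {sorted(candidates)}")
print(f"worst-case status: {assignment.status} ({assignment.concern})")
# NT and below count as least concern; VU or higher is conservation concern.
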