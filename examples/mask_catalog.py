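"""Enumerate the HLAC mask sets and show how they are organized.

Prints the cardinality of the full gray-scale set (35), the adopted
repeated-pixel-free set (25) with its order grouping, and the JSON form of
a few masks.  The order-0 mask sums raw intensity; the four order-1 masks
measure directional pairwise correlation; the twenty order-2 masks respond
to lines and curves.
"""

import json

from hlacir import CENTER_NO_REPEAT, FULL_GRAYSCALE, enumerate_masks, excluded_masks

full = enumerate_masks(2, FULL_GRAYSCALE)
reduced = enumerate_masks(2, CENTER_NO_REPEAT)
dropped = excluded_masks(2)

print(f"full gray-scale set : {len(full)} masks")
print(f"adopted set         : {len(reduced)} masks, orders {reduced.order_histogram()}")
print(f"excluded (squares/cubes): {len(dropped)} masks")

catalog = json.loads(reduced.to_json())
for entry in catalog["masks"][:6]:
    offs = ", ".join(
        f"({o['dx']},{o['dy']})x{o['multiplicity']}" for o in entry["offsets"]
    )
    print(f"  mask {entry['index']:2d} (order {entry['order']}): {offs}")
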