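"""First-in-first-out feature memory bank: push, evict, retrieve by
cosine similarity."""

import numpy as np

from mcmunet.model import MemoryBank, bank_query

rng = np.random.default_rng(1)
bank = MemoryBank(capacity=4)

entries = [rng.standard_normal((8, 2, 2)).astype(np.float32) for _ in range(5)]
for i, e in enumerate(entries):
    bank.push(e)
    print(f"push #{i}: bank holds {len(bank)}/{bank.capacity} entries")
print("-> the 5th push evicted the oldest entry (FIFO), capacity never exceeded")

query = entries[3] + 0.01 * rng.standard_normal((8, 2, 2)).astype(np.float32)
top3 = bank_query(query, bank)
print(f"\nquery close to entry #3 -> top-3 bank indices {top3}")
print("(index 2 in the bank is the original entry #3 after one eviction; it is")
print(" ranked first because its pooled channel descriptor is most similar)")
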