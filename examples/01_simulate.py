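"""Generate a small synthetic HIV/cancer record universe.

Builds 2,000 ground-truth persons, emits duplicated and corrupted HIV
laboratory records plus cancer pathology records, and prints what came out.
Every record maps back to its generating entity through the truth table,
which is what makes the downstream linkage testable.
"""

from hivcanlink.config import GeneratorConfig
from hivcanlink import synthgen

cfg = GeneratorConfig(n_entities=2000, seed=7)
data = synthgen.generate(cfg)

print(f"entities:        {len(data.entities):>6}")
print(f"hiv records:     {len(data.hiv):>6}  "
      f"(~{len(data.hiv) / len(data.entities):.2f} per person)")
print(f"cancer records:  {len(data.cancer):>6}  "
      f"(fraction {len(data.cancer) / len(data.entities):.2f})")
print()
print("one person's duplicate HIV records (note identifier noise):")
truth = data.truth.set_index("record_id")["entity_id"]
ent = data.hiv["record_id"].map(truth)
dup_entity = ent.value_counts().index[0]
cols = ["record_id", "first_name", "surname", "dob", "age",
        "episode_number", "province", "test_date", "result_label"]
print(data.hiv[ent == dup_entity][cols].to_string(index=False))
print()
print("The records above all belong to", dup_entity,
      "- same person, possibly different spellings, sometimes a missing "
      "date of birth or episode number. The linkage stage has to undo this.")
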