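"""Classify lineages into metazoan categories and derive a conservation range.

A human-query uORF with representative homologs in mouse (Rodentia),
dog (Carnivora) and fly (Diptera) is conserved out to Insecta.
"""

from cpuorf import assign_category, conservation_profile

MUS = ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
       "Vertebrata", "Euteleostomi", "Sarcopterygii", "Tetrapoda",
       "Mammalia", "Eutheria", "Euarchontoglires", "Rodentia")
CANIS = MUS[:11] + ("Laurasiatheria", "Carnivora")
FLY = ("Metazoa", "Eumetazoa", "Bilateria", "Protostomia", "Ecdysozoa",
       "Arthropoda", "Insecta", "Diptera")

for name, lineage in [("mouse", MUS), ("dog", CANIS), ("fly", FLY)]:
    print(f"{name:>6}: {assign_category(lineage)}")


class Hit:
    def __init__(self, subject_id):
        self.subject_id = subject_id


reps = {"Rodentia": Hit("r1"), "Carnivora": Hit("c1"), "Diptera": Hit("f1")}
lineages = {"r1": MUS, "c1": CANIS, "f1": FLY}
profile = conservation_profile(reps, "my_uorf", "Euarchontoglires", lineages)

print()
print("category counts:", profile.category_counts)
print("taxonomic range:", profile.range_label)
print()
print("The range is the most distal non-empty category relative to the")
print("query's own category (Euarchontoglires for a human gene).")
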