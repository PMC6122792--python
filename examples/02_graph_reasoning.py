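"""Reason about the network structure without touching any data.

The DAG alone determines which variables are directly associated (Markov
blankets) and which sets are conditionally independent (d-separation), and
it factorizes the 19-variable joint density into small local pieces.
"""

import behavnet as bn

graph = bn.study_structure("total_pa")

print("joint density factorization:")
print(" ", bn.factorization(graph))
print("\nmax in-degree:", bn.max_in_degree(graph),
      "- no variable has more than 3 direct influences")

for node in ("loginsulin", "logcrp", "BMI", "PA"):
    print(f"Markov blanket of {node}: {sorted(bn.markov_blanket(graph, node))}")
print("given its blanket, each variable is independent of everything else")

mental = {"Insomnia", "Depression", "QOLm"}
physical = {"BMI", "PA", "QOLp", "loginsulin", "logcrp"}
sep = bn.d_separated(graph, mental, physical, {"Sleep2", "Arthritis"})
print(f"\nmental cluster _||_ physical cluster | (Sleep2, Arthritis): {sep}")
print("sleep impairment is the hub connecting mental health to physical health")
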