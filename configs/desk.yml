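# "Desk" profile: a scaled-down world that runs on a single workstation.
# Full-scale experiments use the defaults (K = 160, 10,000 generations,
# 50 replicates); this profile shrinks the demes, horizon and replication
# while keeping the genetic architecture intact.
#
# Sweep it over the interesting cells with, e.g.:
#   polyandrysim run -c configs/desk.yml -o out/desk \
#       --sweep-s 0,0.03 --sweep-d 0.001,0.1 \
#       --modes evolving_polyandry,fixed_monandry
carrying_capacity: 60
generations: 1500
replicates: 10
dispersal_probability: 0.001
selection_coefficient: 0.03
record_every: 10
correlation_window: 50
master_seed: 1
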