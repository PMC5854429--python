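# Stage 2: the hand-off system with the two outermost beads of each arm
# removed (their sites gone), covering the remaining unwrapping range.
stage_id = "stage2"
seed = 6

[system]
type = "mimic"

[system.spec]
n_beads = 2
n_sites = 1
site_energies = [0.8]
site_beads = [0]
friction = 0.5

[abmd]
range = [20.0, 60.0]
walls = [22.0, 58.0]
tau = 1.0
n_walkers = 8
duration = 120.0
record_interval = 20

[umbrella]
lo = 24.0
hi = 56.0
spacing = 2.0
k = 0.3
duration = 150.0
record_interval = 20
burn_in = 30.0

[wham]
bin_width = 1.0

[metrics]
count_mode = "any"
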