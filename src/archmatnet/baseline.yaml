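# Baseline configuration for OFAT sweeps (one tick = one month).
nTicks: 2000
nBands: 3
campPopulation: 10
pEnvChange: 0.05
envMode: mutating
aggregationFreq: 0.02
aggregationDuration: 5
pHunting: 0.05
huntingGroupSize: 5
pVisiting: 0.05
pNewAlliance: 0.05
maximumAlliesN: 5
pMigration: 0.002
genderedMigration: false
pTrading: 0.1
transmissionRate: 0.1
learningMethod: prestige
pLuckyLeap: 0.005
pNewVariant: 0.01
pNewObject: 0.1
pLoss: 0.01
potteryPrestige: random_values
uniqueTraits: false
visibility: false
pDropPot: 0.05
pDropPoint: 0.05
migrationOnsetTick: 1000
snapshotInterval: 1000
randomSeed: 42
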