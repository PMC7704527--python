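{
  "validation_set.csv": "093bb7ee5f822b18f5bbed3abe8089aae9aecb293236a4114ff4bcce902e89e9",
  "model1_predictions.csv": "50ebfde9461152f590b738ba749ae9b8010f991f09d458075969c9ce608af91f",
  "designed_properties.csv": "dc8984fe508433a27ba74c2672165d9f20e2d55e82deaf0a9558250072e6cf4e",
  "published_models.json": "1a22224e8a2f4ffdd1c0b3147bf89383187a75c4263999cb7dd737cd873acc31"
}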