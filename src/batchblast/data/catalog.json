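[
  {"name": "c5ad.4xlarge",  "provider": "aws", "vcpus": 16, "ram_gib": 32,  "hourly_price": 0.688,   "spot_discount": 0.3, "local_ssd_gib": 600},
  {"name": "r5ad.4xlarge",  "provider": "aws", "vcpus": 16, "ram_gib": 128, "hourly_price": 1.048,   "spot_discount": 0.3, "local_ssd_gib": 600},
  {"name": "r5ad.24xlarge", "provider": "aws", "vcpus": 96, "ram_gib": 768, "hourly_price": 6.288,   "spot_discount": 0.3, "local_ssd_gib": 3600},
  {"name": "e2-highmem-8",  "provider": "gcp", "vcpus": 8,  "ram_gib": 64,  "hourly_price": 0.40716, "spot_discount": 0.2, "local_ssd_gib": 375},
  {"name": "e2-highmem-16", "provider": "gcp", "vcpus": 16, "ram_gib": 128, "hourly_price": 0.81432, "spot_discount": 0.2, "local_ssd_gib": 375},
  {"name": "n1-highmem-96", "provider": "gcp", "vcpus": 96, "ram_gib": 624, "hourly_price": 5.6832,  "spot_discount": 0.2, "local_ssd_gib": 3000}
]
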