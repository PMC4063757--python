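235dfe61b202a7d8ac94cf7327c27ea3decb4145351fe87ab322ff7b398e39d2  anterior_left.csv
4f1a3cb14f67ea0c73b8a4efe47bfd9daca1ef7549fbc456ce6fd0428192e1ae  anterior_right.csv
32ddf3451dd8206626851d904a9c03d8d6c51121309de6ee0622f0095668b5ab  posterior_left.csv
70a0985e037b81a9d2565fb4e3ba8bddb7a23e2b7ca50c5447b682929d6e794f  posterior_right.csv
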