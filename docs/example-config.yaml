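# Example training configuration for `charner train --config ...`.
# Flat key/value document; command-line flags override these values.
# Defaults shown are the package's reference settings.

word_dim: 50          # dimension of the (pre-trained) word embeddings
char_dim: 30          # character embedding dimension; init uniform [0, 1)
char_hidden_dim: 50   # hidden layer of the character attention
hidden_dim: 100       # LSTM hidden units per direction
combiner_dim: 100     # tanh layer merging the two LSTM directions
word_window: 2        # token context half-width (x_i spans 2w+1 tokens)
char_window: 2        # character context half-width inside the attention
learning_rate: 0.01   # AdaGrad base rate alpha
l2: 1.0e-08           # ridge coefficient lambda
max_epochs: 100
patience: 10          # epochs without dev-F1 improvement before stopping
seed: 0

# architectural switches
decoder: crf          # crf | softmax (per-position argmax, no transitions)
use_char: true        # attention-composed character representation
bidirectional: true   # forward + backward LSTM
fine_tune_words: true # update the word embeddings during training
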